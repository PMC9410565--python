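# Methods

## Data model and normalization

The atomic input is a spot-by-gene integer count matrix with integer array
coordinates per spot barcode. Coordinates are in array units: one unit is
one spot pitch (200 μm center-to-center on the classical ST array; spots
are 100 μm across), so graph hop distances translate directly to physical
distance. Spots whose total counts fall below `min_counts` (default 1,
i.e. zero-count spots) are treated as *empty* array positions: removed
from the analysis matrix but remembered, because empty positions must
break adjacency in the graph. The threshold is configurable since the
boundary between "failed spot" and "sparse tissue" is platform-dependent.

Counts are TP10K-normalized (each spot rescaled to 10,000 total counts),
without log transform; both marker-mean and AUC scoring consume the linear
TP10K matrix, and an optional `log1p` flag exists for users who want
log-scale values. Gene symbols are matched case-sensitively after
whitespace stripping; alias resolution is out of scope because alias
tables are external data.

## Neighborhood connectivity graph

Nodes are occupied spots; edges join adjacent spots with equal weight.
Default adjacency is **queen** (8-neighbor): with 100 μm spots on a 200 μm
pitch, diagonal neighbors are only √2 ≈ 1.41 pitches apart and plausibly
in physical contact, so queen is the better proxy for tissue contiguity;
rook (4-neighbor) is available via config. Adjacency is strictly offset-1
among occupied positions — two occupied spots separated by an empty
position are never connected, at axis or diagonal offsets alike. Radius
and length-pruned Delaunay graphs are provided for non-grid platforms;
collinear input falls back to the radius graph.

Two weight matrices serve different statistics:

- `W_binary` (symmetric 0/1) for Moran's I, where all edges carry equal
  weight;
- `W_row` (row-standardized) for spatial PCA and the lag model, whose
  parameter space and eigen-identities require unit row sums.

Disconnected graphs: global statistics are computed over the full node
set, but the lag model refuses graphs whose largest connected component
holds < 90% of nodes, because ρ is not comparable across fragmented
graphs. Isolated nodes are retained with a warning.

## Scores

Cell-type abundance is the mean TP10K expression of the type's marker
genes at each spot; markers absent from the matrix are excluded and
logged, and a type with no present marker is an error.

Pathway activity is a recovery-curve AUC. Per spot, all genes are ranked
by decreasing TP10K value, with ties broken by one seeded random
permutation applied before ranking (shared across spots, so scores are
reproducible and permutation-invariant given the seed). With
`maxRank = ceil(top_frac · n_genes)` (default `top_frac` 0.05, the
conventional default for this score family) and `hits(r)` the number of
set genes at rank ≤ r, the raw AUC is `Σ_{r=1..maxRank} hits(r)`
(rectangle integration of the right-continuous step curve), normalized by
the perfect-ranking AUC `Σ min(r, |set ∩ universe|)`, giving scores in
[0, 1]. The brute-force step-curve definition — not any external tool —
is the reference the tests integrate against.

## Moran's I and inference

`I = (N/W) Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)²` with `wᵢᵢ = 0` and
`W = Σ wᵢⱼ`, evaluated exactly (constant x is an error: zero variance).
Inference permutes the values over the nodes; the p-value uses the
add-one correction `p = (1 + #extreme)/(n_perm + 1)` and is two-sided by
default, measuring extremeness as distance from the null expectation
−1/(N−1); one-sided alternatives are available. The tests verify the
vectorized statistic against a literal double-loop evaluation of the
formula, the exact −1 of a checkerboard, and the permutation-null mean
against −1/(N−1).

## Semivariogram

`γ(d)` is half the mean squared difference over unordered node pairs at
graph hop distance **exactly** d (not ≤ d), for d = 1..d_max. Hop counts
are used as the lag axis so that "d units" means "d spots ≈ d·200 μm";
lags with fewer than `min_pairs` (default 30) pairs are reported with
their pair count but no γ, to avoid noisy tail estimates. White noise is
flat at the field variance; strongly autocorrelated fields rise over lags
1–4, and the package reports both raw γ(d) and the ratio γ(d)/γ(1)
without imposing any baseline-lag convention.

## Spatial PCA

With X the centered (by default also unit-variance) score matrix and W
row-standardized, sPCA eigendecomposes `Ω = (1/2n)·Xᵀ(W+Wᵀ)X`. For every
component, `λₖ = var(scoreₖ)·I(scoreₖ)` holds exactly (verified to 1e-8
in tests): large positive eigenvalues are smooth regional structure,
negative eigenvalues local contrast. Feature scaling defaults on so cell
types with different score magnitudes contribute comparably. At least two
nonconstant features are required; zero-variance features are dropped
with a warning, and a table that leaves fewer than two is an error, so a
"single-feature sPCA" is deliberately not exposed (its eigenvalue would
just be var·I of that feature).

## Spatial-lag regression

`y = ρWy + Xβ + ε, ε ~ N(0, σ²I)` fit by maximum likelihood. For a
candidate ρ, `β̂(ρ)` and `σ̂²(ρ)` have closed forms and the concentrated
log-likelihood is `−(n/2)(ln 2πσ̂² + 1) + Σᵢ ln(1−ρλᵢ)`, with λᵢ the
eigenvalues of W_row obtained through the similarity transform
`D^{-1/2} A D^{-1/2}` (real spectrum for symmetric adjacency; isolated
nodes contribute zeros). ρ̂ is found by bounded scalar optimization over
the feasible interval `(1/λ_min, 1)`; an estimate within 1e-6 of a
boundary is flagged. Standard errors come from the inverse negative
numerical Hessian (central differences) of the full log-likelihood in
(ρ, β, σ²); per-coefficient p-values are two-sided Wald. At ρ = 0 the
concentrated likelihood equals the ordinary-least-squares value exactly,
which the tests assert against an independent OLS fit, and ρ̂ is
cross-checked against a dense 1e-4 grid search of the likelihood.

The pathway batch (`fit_all_pathways`) standardizes cell-type predictors
to mean 0, SD 1 (so coefficients are per-SD effects), keeps the response
on its native scale, and emits a long coefficient table plus the
pathway × cell-type p-value matrix. Wald p-values match a per-coefficient
heatmap presentation; no correction is applied to the matrix itself, but
a Benjamini–Hochberg column over the cell-type coefficients is emitted
for users. Failed fits are recorded per pathway, never fatal to the
batch.

## CNV subclones

The profile follows the classic expression-smoothing recipe: log2(TP10K+1);
subtract the per-gene mean over reference (non-malignant) spots; order
genes along the genome; centered moving average of `window` genes (default
101, the customary denoising width) within each chromosome with truncated
edge windows; subtract each spot's median; clip to ±`clip` (default 1.0
log2 units). Genes without genomic positions are flagged and excluded;
genes expressed in < 5% of spots are filtered first. HMM-style state
calling is out of scope — the output is a relative, smoothed profile.

Because spots mix cell types, no per-spot "ductal cell" label exists;
reference spots are chosen as those at or below a tumor-score quantile
(default median), a stand-in recorded in output metadata. Tumor-rich
spots (above the quantile) are Ward-clustered on Euclidean distances
between profile rows; K ∈ [2, 4] is selected by maximum mean silhouette,
falling back to the smallest K with a warning when profiles are
degenerate. Labels are mapped back to array coordinates for rendering.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical regime of spot-level tumor
spatial transcriptomics: a 24×24 array at 85% occupancy (~490 occupied
spots, within the few-hundred regime of classical ST), 20–70 cells per
spot at 100 counts per cell (spot libraries of 2,000–7,000), an
8-type panel (tumor, fibroblast, stellate, acinar, ductal, myeloid, T, B),
Poisson counts, marker genes at 10-fold within-type elevation, four
pathway modules of 20 genes, 260 background genes over 10 chromosomes,
and 3 subclones with whole-chromosome ±1 log2 events partitioned by
nearest-seed geometry within the tumor-rich half of the section.

Latent abundance fields are **simultaneous autoregressive (SAR)**,
`z = (I − ρW_row)⁻¹ε`, deliberately matching the lag model's generating
process so that ρ-recovery can be tested directly. For composition,
fields are rescaled to a stated *marginal* SD before entering the
softmax: the raw SAR transform inflates marginal variance as ρ → 1, and
without rescaling the tumor field dominates the softmax denominator and
smears its smooth structure into every other type's proportions.
Clustered types use marginal SD 1.0; dispersed immune types use 1.3,
reflecting that immune infiltration is the most variable compartment
spot-to-spot. With these conditions the generated samples show tumor
Moran's I ≈ 0.38–0.66 and immune |I| < 0.1 — the clustered-tumor /
dispersed-immune contrast the analysis targets.

Not emulated: tissue morphology (ducts, stroma geometry), platform noise
(spot bleed, capture-efficiency gradients), overdispersion beyond Poisson
(negative-binomial dispersion is exposed in no default path), or
cross-sample clone sharing. Passing tests therefore demonstrate
statistical correctness of the methods under their own assumptions, not
robustness to real-platform artifacts.

Softmax composition (rather than Dirichlet) keeps each type's spatial
structure independently controllable, but closure still couples types
weakly: a perfectly dispersed type inherits a small positive I (≈ 0.02–0.06
under defaults) from the smooth types through the shared denominator.
This is a property of compositional data, not an artifact of the
implementation.

## Numerical choices and problem sizes

- Permutation tests default to 999 permutations, two-sided, add-one
  corrected; the p-value floor is 1/(n_perm+1).
- ρ optimization uses `xatol` 1e-10 on the bounded interval; Hessian
  steps are 1e-5 relative.
- Hierarchical clustering uses Ward linkage on Euclidean distances;
  silhouette selects K.
- Simulation-based tests use 14×14 to 24×24 grids, 20–50 replicates per
  property, and fixed seeds throughout; these sizes make each property
  decisive (recovery margins far exceed Monte-Carlo noise) while the full
  suite stays fast.
- All randomness flows from explicit seeds through `numpy` generators or
  spawned `SeedSequence` children in fixed order; outputs are
  byte-reproducible under a fixed master seed.

## Known limitations

- Moran's I inference is permutation-based only; no analytic variance
  (normality or randomization moments) is reported.
- The lag model assumes homoskedastic Gaussian errors and a shared ρ
  across the section; spatial-error and Durbin variants are out of scope.
- CNV profiles are relative to the chosen reference spots; a biased
  reference (e.g. tumor contamination) shifts all profiles.
- Local spatial indicators (LISA, Getis–Ord) and variogram model fitting
  (sill/range estimation) are not implemented; only global statistics and
  empirical curves are reported.
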