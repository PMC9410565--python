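# spatialtme

Graph-based spatial statistics for quantifying tumor-microenvironment (TME)
heterogeneity in spot-level spatial transcriptomics.

Spatial transcriptomics arrays profile a few hundred to a thousand spots per
tissue section, each spot aggregating the transcripts of roughly 20–70 cells
at a known (x, y) array position. Adjacent tissue regions are not independent
observations, and tissue architecture makes contact relationships more
meaningful than raw Euclidean distance. `spatialtme` therefore projects the
spots onto a **neighborhood connectivity graph** — occupied spots are nodes,
spatially adjacent spots are joined by equal-weight edges, and empty array
positions break adjacency — and applies spatial statistics on that graph:

- **Cell-type abundance scores**: per-spot mean TP10K expression of marker
  genes; **pathway activity scores**: ranking-based recovery-curve AUC of a
  gene set among each spot's top-expressed genes.
- **Moran's I** with permutation inference,

  `I = (N/W) · Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)²`,

  to ask whether a score clusters among neighboring spots (null expectation
  −1/(N−1)).
- **Semivariograms** over graph hop distance,
  `γ(d) = ½·mean[(xᵢ−xⱼ)² : hop(i,j)=d]`, to measure how association decays
  with distance in spot units.
- **Spatial PCA**: eigenanalysis of the symmetric lagged covariance
  `Ω = (1/2n)·Xᵀ(W+Wᵀ)X`; each eigenvalue factors exactly as
  `λₖ = var(scoreₖ)·I(scoreₖ)`, separating globally smooth from locally
  contrasting multivariate structure.
- **Spatial-lag regression** `y = ρWy + Xβ + ε` by concentrated maximum
  likelihood, modeling pathway activity as a function of cell-type
  abundances while absorbing neighborhood autocorrelation into ρ.
- **Expression-based CNV subclones**: reference-centered, genome-ordered,
  moving-average-smoothed log2 expression profiles, Ward-clustered into 2–4
  subclones mapped back onto the array.

A fully deterministic synthetic-data generator (`spatialtme.simulate`)
produces datasets with the statistical structure these analyses assume —
spatially autocorrelated tumor/fibroblast fields, dispersed immune types,
pathway modules, planted subclones — together with the generating ground
truth, so every stage is testable without external downloads.

## Worked example

```sh
spatialtme simulate --out demo/sim --seed 2
spatialtme stats --counts demo/sim/counts.tsv --coords demo/sim/coords.tsv \
    --markers demo/sim/markers.tsv --feature tumor --n-perm 999
```

or in Python:

```python
from spatialtme import (SimulationConfig, simulate_dataset,
                        cell_type_scores, morans_i, semivariogram)

sample = simulate_dataset(SimulationConfig(seed=2))
scores = cell_type_scores(sample.dataset, sample.markers)
for t in ("tumor", "fibroblast", "myeloid", "tcell"):
    print(t, round(morans_i(scores.vector(t), sample.graph), 3))
```

prints

```
tumor 0.495
fibroblast 0.29
myeloid 0.002
tcell 0.002
```

Tumor abundance is strongly spatially autocorrelated (I ≈ 0.5, permutation
p = 0.001 at 999 permutations) and the immune scores sit at the null — the
clustered-tumor / dispersed-immune contrast the method is designed to
quantify. The semivariogram of the tumor score rises steadily over hop
distances 1–5 (+106% relative to lag 1 for this seed), the graph-distance
signature of regional tumor organization.

The full pipeline (scores → graph → Moran/variogram → spatial PCA →
lag models → subclones, with figures and a checksummed run manifest):

```sh
spatialtme run --config run.yaml --out demo/out
```

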