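"""Synthetic spot datasets with known spatial structure.

The generator emulates the statistical regime of classical spatial
transcriptomics of solid tumors: a few hundred occupied spots on a square
array (200 um pitch), each spot aggregating the transcripts of 20-70 cells
from a mixture of cell types.  Tumor and fibroblast abundance follow
spatially autocorrelated latent fields; immune types are spatially
dispersed.  On top of the mixture sit pathway gene modules coupled to
latent fields, and 2-4 spatially localized subclones carrying
chromosome-scale copy-number shifts.

Latent fields are simultaneous-autoregressive (SAR):

    z = (I - rho * W_row)^{-1} eps,   eps ~ N(0, sd^2 I)

so the generating ``rho`` is the same parameter the spatial-lag model
estimates, which makes direct parameter-recovery tests possible.  Cell-type
proportions are a softmax over (offset_t + z_t); spot counts are Poisson
with rate = library_size * mixture expression, modulated by pathway factors
exp(effect * latent) and CNV factors 2^shift on the affected chromosome.

Everything is deterministic under the master seed, and every latent
quantity is returned in a :class:`GroundTruth` record so each analysis
stage can be tested against what was actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.sparse import eye as speye
from scipy.sparse.linalg import spsolve

from .graph import NeighborGraph, grid_graph_from_coords
from .io import (
    GenePositionTable,
    GeneSetCollection,
    MarkerSet,
    SpotDataset,
    tp10k_normalize,
    write_gene_positions,
    write_gmt,
    write_marker_table,
    write_spot_dataset,
)

__all__ = [
    "CellTypeSpec",
    "PathwaySpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedSample",
    "simulate_sar_field",
    "simulate_dataset",
    "write_sample",
]


@dataclass
class CellTypeSpec:
    """One cell type's latent spatial field and abundance baseline."""

    rho: float = 0.0        # SAR coefficient of the latent abundance field
    sd: float = 1.0         # innovation SD of the field
    offset: float = 0.0     # softmax baseline (log-abundance offset)


@dataclass
class PathwaySpec:
    """A pathway gene module and the latent field driving its activity.

    ``couple_to`` names a cell type whose latent field drives the module;
    ``"independent"`` gives the module its own SAR field with coefficient
    ``rho``.  Module genes are multiplied by exp(effect * latent).
    """

    n_genes: int = 20
    couple_to: str = "independent"
    rho: float = 0.8
    effect: float = 0.6


def _default_cell_types() -> dict[str, CellTypeSpec]:
    """The pancreatic-tumor cell-type panel the generator emulates.

    Tumor and fibroblast abundance is spatially clustered (high SAR rho),
    the stromal types mildly so, and the immune types (myeloid, T, B) are
    spatially dispersed (rho = 0) with a larger marginal SD — immune
    infiltration is the most variable compartment spot-to-spot.
    """
    return {
        "tumor": CellTypeSpec(rho=0.9, sd=1.0, offset=0.4),
        "fibroblast": CellTypeSpec(rho=0.7, sd=1.0, offset=0.0),
        "stellate": CellTypeSpec(rho=0.5, sd=1.0, offset=-0.2),
        "acinar": CellTypeSpec(rho=0.4, sd=1.0, offset=-0.2),
        "ductal": CellTypeSpec(rho=0.4, sd=1.0, offset=0.0),
        "myeloid": CellTypeSpec(rho=0.0, sd=1.3, offset=-0.3),
        "tcell": CellTypeSpec(rho=0.0, sd=1.3, offset=-0.3),
        "bcell": CellTypeSpec(rho=0.0, sd=1.3, offset=-0.5),
    }


def _default_pathways() -> dict[str, PathwaySpec]:
    return {
        "hypoxia": PathwaySpec(n_genes=20, couple_to="independent", rho=0.8, effect=0.6),
        "cell_cycle": PathwaySpec(n_genes=20, couple_to="tumor", effect=0.5),
        "emt": PathwaySpec(n_genes=20, couple_to="fibroblast", effect=0.5),
        "inflammation": PathwaySpec(n_genes=20, couple_to="myeloid", effect=0.5),
    }


@dataclass
class SimulationConfig:
    """Generator parameters; the defaults are the package's study conditions.

    A 24 x 24 array at 85% occupancy yields ~490 occupied spots, in the
    middle of the few-hundred-spot regime of classical ST arrays; each spot
    aggregates 20-70 cells at 100 counts per cell.
    """

    grid_rows: int = 24
    grid_cols: int = 24
    occupancy: float = 0.85
    adjacency: str = "queen"
    cell_types: dict[str, CellTypeSpec] = field(default_factory=_default_cell_types)
    markers_per_type: int = 10
    marker_fold: float = 10.0
    pathways: dict[str, PathwaySpec] = field(default_factory=_default_pathways)
    background_genes: int = 260
    cells_min: int = 20
    cells_max: int = 70
    depth_per_cell: int = 100
    n_chromosomes: int = 10
    n_subclones: int = 3
    cnv_shift: float = 1.0   # |log2 shift| of each clone's chromosome event
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        for name, ct in self.cell_types.items():
            if isinstance(ct, dict):
                self.cell_types[name] = ct = CellTypeSpec(**ct)
            if not 0.0 <= ct.rho < 1.0:
                raise ValueError(f"cell type {name}: rho must be in [0, 1)")
        for name, pw in self.pathways.items():
            if isinstance(pw, dict):
                self.pathways[name] = pw = PathwaySpec(**pw)
            if pw.couple_to != "independent" and pw.couple_to not in self.cell_types:
                raise ValueError(f"pathway {name} couples to unknown type {pw.couple_to!r}")
        if not 2 <= self.n_subclones:
            raise ValueError("need at least 2 subclones")

    @property
    def n_genes(self) -> int:
        return (
            self.markers_per_type * len(self.cell_types)
            + sum(p.n_genes for p in self.pathways.values())
            + self.background_genes
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    latent_fields: pd.DataFrame       # spots x cell types
    proportions: pd.DataFrame         # spots x cell types, rows sum to 1
    pathway_latents: pd.DataFrame     # spots x pathways
    subclone_labels: pd.Series        # 0 = no clone (reference side)
    subclone_chromosomes: dict[int, tuple[str, float]]  # clone -> (chrom, log2 shift)
    cells_per_spot: np.ndarray
    n_occupied: int
    config: SimulationConfig


@dataclass
class SimulatedSample:
    dataset: SpotDataset
    markers: MarkerSet
    genesets: GeneSetCollection
    positions: GenePositionTable
    graph: NeighborGraph
    truth: GroundTruth


def simulate_sar_field(graph: NeighborGraph, rho: float, sd: float, seed: int) -> np.ndarray:
    """Draw one SAR field z = (I - rho W_row)^{-1} eps on the graph."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho={rho} outside the feasible interval [0, 1)")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sd, size=graph.n_nodes)
    if rho == 0.0:
        return eps
    A = speye(graph.n_nodes, format="csc") - rho * graph.W_row.tocsc()
    return np.asarray(spsolve(A, eps))


def _standardized_field(graph, rho, sd, seed) -> np.ndarray:
    """SAR field rescaled to marginal SD ``sd``.

    The raw SAR transform inflates the marginal variance as rho -> 1; for
    mixture logits the interpretable knob is the marginal spread of the
    field, so cell-type and pathway latents are standardized after the draw.
    """
    z = simulate_sar_field(graph, rho, 1.0, seed)
    return sd * (z - z.mean()) / z.std()


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=1, keepdims=True)


def _farthest_point_seeds(coords: np.ndarray, k: int, rng) -> list[int]:
    """Greedy maximally spread seed spots for the subclone partition."""
    first = int(rng.integers(len(coords)))
    seeds = [first]
    d = np.linalg.norm(coords - coords[first], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return seeds


def simulate_dataset(config: SimulationConfig) -> SimulatedSample:
    """Generate one complete synthetic sample with ground truth.

    All randomness derives from ``config.seed`` through spawned seed
    sequences in a fixed order, so the output is fully deterministic.
    """
    types = list(config.cell_types)
    if config.markers_per_type * len(types) > config.n_genes:
        raise ValueError("more marker genes requested than genes available")
    ss = np.random.SeedSequence(config.seed)
    (s_grid, s_fields, s_pathways, s_clones, s_counts, s_positions) = ss.spawn(6)

    # --- occupancy mask and graph -------------------------------------------
    rng_grid = np.random.default_rng(s_grid)
    xs, ys = np.meshgrid(np.arange(config.grid_cols), np.arange(config.grid_rows))
    all_coords = np.column_stack([xs.ravel(), ys.ravel()])
    occupied = rng_grid.random(len(all_coords)) < config.occupancy
    coords = all_coords[occupied]
    if len(coords) < 2:
        raise ValueError("occupancy too low: fewer than 2 occupied spots")
    barcodes = [f"spot_{x}x{y}" for x, y in coords]
    graph = grid_graph_from_coords(coords, barcodes, adjacency=config.adjacency)
    n = len(barcodes)

    # --- latent cell-type fields and proportions ----------------------------
    field_seeds = s_fields.spawn(len(types))
    fields = {}
    for t, child in zip(types, field_seeds):
        spec = config.cell_types[t]
        fields[t] = _standardized_field(
            graph, spec.rho, spec.sd, seed=child.generate_state(1)[0] % (2**31)
        )
    latent = pd.DataFrame(fields, index=barcodes)
    logits = latent.to_numpy() + np.array([config.cell_types[t].offset for t in types])
    proportions = pd.DataFrame(_softmax(logits), index=barcodes, columns=types)

    # --- gene universe -------------------------------------------------------
    genes: list[str] = []
    markers = {t: [f"{t.upper()}_M{i}" for i in range(config.markers_per_type)] for t in types}
    for t in types:
        genes += markers[t]
    modules = {}
    for pw, spec in config.pathways.items():
        modules[pw] = [f"{pw.upper()}_G{i}" for i in range(spec.n_genes)]
        genes += modules[pw]
    genes += [f"BG_{i}" for i in range(config.background_genes)]
    n_genes = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}

    # per-type expression profiles: markers at `marker_fold`, rest at 1
    profiles = np.ones((len(types), n_genes))
    for ti, t in enumerate(types):
        profiles[ti, [gidx[g] for g in markers[t]]] = config.marker_fold
    profiles /= profiles.sum(axis=1, keepdims=True)

    # --- pathway latents -----------------------------------------------------
    pw_seeds = s_pathways.spawn(len(config.pathways))
    pw_latent = {}
    for (pw, spec), child in zip(config.pathways.items(), pw_seeds):
        if spec.couple_to == "independent":
            pw_latent[pw] = _standardized_field(
                graph, spec.rho, 1.0, seed=child.generate_state(1)[0] % (2**31)
            )
        else:
            pw_latent[pw] = latent[spec.couple_to].to_numpy()
    pw_latent = pd.DataFrame(pw_latent, index=barcodes)

    # --- gene genomic positions (shuffled, contiguous chromosome blocks) ----
    rng_pos = np.random.default_rng(s_positions)
    shuffled = list(rng_pos.permutation(genes))
    per_chrom = int(np.ceil(n_genes / config.n_chromosomes))
    chrom_of = {}
    rows = []
    for i, g in enumerate(shuffled):
        c = f"chr{i // per_chrom + 1}"
        chrom_of[g] = c
        start = (i % per_chrom) * 1000 + 1
        rows.append((g, c, start, start + 500))
    positions = GenePositionTable(
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).set_index("gene")
    )

    # --- subclones ------------------------------------------------------------
    rng_clone = np.random.default_rng(s_clones)
    p_tumor = proportions["tumor"].to_numpy() if "tumor" in proportions else proportions.iloc[:, 0].to_numpy()
    tumor_high = p_tumor > np.median(p_tumor)
    clone_labels = np.zeros(n, dtype=int)
    tumor_idx = np.flatnonzero(tumor_high)
    seeds = _farthest_point_seeds(coords[tumor_idx].astype(float), config.n_subclones, rng_clone)
    seed_coords = coords[tumor_idx][seeds].astype(float)
    nearest = np.argmin(
        np.linalg.norm(coords[tumor_idx, None, :].astype(float) - seed_coords[None], axis=2),
        axis=1,
    )
    clone_labels[tumor_idx] = nearest + 1
    clone_events = {
        k: (f"chr{k}", config.cnv_shift * (1 if k % 2 == 1 else -1))
        for k in range(1, config.n_subclones + 1)
    }

    cnv_factor = np.ones((n, n_genes))
    for k, (chrom, shift) in clone_events.items():
        gcols = [gidx[g] for g in genes if chrom_of[g] == chrom]
        rows_k = clone_labels == k
        if rows_k.any() and gcols:
            cnv_factor[np.ix_(rows_k, gcols)] = 2.0 ** shift

    # --- rates and counts ----------------------------------------------------
    rng_counts = np.random.default_rng(s_counts)
    cells = rng_counts.integers(config.cells_min, config.cells_max + 1, size=n)
    lib = cells * config.depth_per_cell
    mixture = proportions.to_numpy() @ profiles          # spots x genes
    pw_factor = np.ones((n, n_genes))
    for pw, spec in config.pathways.items():
        cols = [gidx[g] for g in modules[pw]]
        pw_factor[:, cols] *= np.exp(spec.effect * pw_latent[pw].to_numpy())[:, None]
    rate = lib[:, None] * mixture * pw_factor * cnv_factor
    counts = rng_counts.poisson(rate)

    dataset = SpotDataset(
        counts=counts.astype(np.int64),
        coords=coords,
        barcodes=barcodes,
        genes=genes,
        empty_coords=all_coords[~occupied],
    )
    dataset = tp10k_normalize(dataset)

    truth = GroundTruth(
        latent_fields=latent,
        proportions=proportions,
        pathway_latents=pw_latent,
        subclone_labels=pd.Series(clone_labels, index=barcodes, name="subclone"),
        subclone_chromosomes=clone_events,
        cells_per_spot=cells,
        n_occupied=n,
        config=config,
    )
    return SimulatedSample(
        dataset=dataset,
        markers=MarkerSet(markers),
        genesets=GeneSetCollection(modules),
        positions=positions,
        graph=graph,
        truth=truth,
    )


def write_sample(sample: SimulatedSample, out_dir, fmt: str = "tsv") -> dict[str, str]:
    """Write a simulated sample in exactly the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = out / ("counts.mtx" if fmt == "mtx" else "counts.tsv")
    paths = {
        "counts": str(counts),
        "coords": str(out / "coords.tsv"),
        "markers": str(out / "markers.tsv"),
        "genesets": str(out / "pathways.gmt"),
        "positions": str(out / "gene_positions.tsv"),
        "truth_proportions": str(out / "truth_proportions.tsv"),
        "truth_subclones": str(out / "truth_subclones.tsv"),
    }
    write_spot_dataset(sample.dataset, counts, paths["coords"], fmt=fmt)
    write_marker_table(sample.markers, paths["markers"])
    write_gmt(sample.genesets, paths["genesets"])
    write_gene_positions(sample.positions, paths["positions"])
    sample.truth.proportions.to_csv(paths["truth_proportions"], sep="\t")
    sample.truth.subclone_labels.to_frame().to_csv(paths["truth_subclones"], sep="\t")
    return paths
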