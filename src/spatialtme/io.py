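"""Readers, writers and normalization for spot-level spatial expression data.

The atomic input of the whole pipeline is a :class:`SpotDataset`: an integer
count matrix (spots x genes) plus integer array-grid coordinates for each
spot barcode.  Coordinates are in array units — one unit is one spot pitch
(200 um center to center on the classical ST array; spots are 100 um wide).

Supported on-disk formats:

* counts — MatrixMarket triplet (``.mtx``, genes x spots, with
  ``<stem>.genes.txt`` / ``<stem>.barcodes.txt`` name sidecars) or TSV
  (orientation auto-detected against the coordinate table);
* coordinates — TSV with columns ``barcode``, ``x``, ``y``;
* marker tables — two-column TSV ``cell_type<TAB>gene``;
* gene sets — standard GMT;
* gene positions — BED-like 4-column TSV ``gene chrom start end``.

Normalization is TP10K: each spot's counts rescaled to a total of 10,000.
Scoring consumes the TP10K matrix directly (no log transform); an optional
``log1p`` flag exists for users who want log-scale values.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix, issparse

logger = logging.getLogger(__name__)

__all__ = [
    "SpotDataset",
    "MarkerSet",
    "GeneSetCollection",
    "GenePositionTable",
    "read_spot_dataset",
    "write_spot_dataset",
    "tp10k_normalize",
    "read_gmt",
    "write_gmt",
    "read_marker_table",
    "write_marker_table",
    "read_gene_positions",
    "write_gene_positions",
]


class SpotDatasetError(ValueError):
    """Raised on invalid spot data (duplicate coordinates, negative counts...)."""


@dataclass
class SpotDataset:
    """Spot-by-gene counts with array coordinates.

    Only *occupied* spots (total counts >= ``min_counts`` at read time) are
    kept in the analysis matrix; spots that failed the threshold are recorded
    in ``empty_coords`` so that graph construction can treat those grid
    positions as holes.

    Attributes
    ----------
    counts : (n_spots, n_genes) int array of raw counts.
    coords : (n_spots, 2) int array of (x, y) grid positions, one per spot.
    barcodes : list of unique spot identifiers, aligned to rows.
    genes : list of unique gene symbols, aligned to columns.
    normalized : (n_spots, n_genes) float array, counts-per-10,000; ``None``
        until :func:`tp10k_normalize` has run.
    empty_coords : (m, 2) int array of grid positions that held a spot below
        the occupancy threshold.
    """

    counts: np.ndarray
    coords: np.ndarray
    barcodes: list[str]
    genes: list[str]
    normalized: np.ndarray | None = None
    empty_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise SpotDatasetError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise SpotDatasetError("barcodes are not unique")
        if len(set(self.genes)) != len(self.genes):
            raise SpotDatasetError("gene symbols are not unique")
        if np.any(self.counts < 0):
            raise SpotDatasetError("negative counts")
        pairs = {tuple(xy) for xy in self.coords}
        if len(pairs) != len(self.coords):
            raise SpotDatasetError("two spots share a coordinate pair")

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def gene_index(self, symbols) -> np.ndarray:
        """Column indices of ``symbols`` present in the gene universe."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array([lookup[s] for s in symbols if s in lookup], dtype=int)


@dataclass
class MarkerSet:
    """Mapping cell_type -> marker gene symbols (lists may overlap)."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        for ct, genes in self.markers.items():
            if len(genes) == 0:
                raise ValueError(f"cell type {ct!r} has no marker genes")

    def __iter__(self):
        return iter(self.markers.items())

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class GeneSetCollection:
    """Mapping pathway name -> gene symbols (de-duplicated, order-preserving)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


_CHROM_RE = re.compile(r"^(?:chr)?(\d+|[XYM]|MT)$", re.IGNORECASE)


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    m = _CHROM_RE.match(chrom)
    if m is None:
        raise ValueError(f"malformed chromosome label {chrom!r}")
    tok = m.group(1).upper()
    if tok.isdigit():
        return (int(tok), "")
    return (1000 + {"X": 0, "Y": 1, "M": 2, "MT": 2}[tok], tok)


@dataclass
class GenePositionTable:
    """Genomic positions establishing a deterministic genome order over genes.

    Chromosomes sort naturally (1..22, X, Y, M) and genes within a chromosome
    by start coordinate, with the gene symbol as the final tie-break.
    """

    table: pd.DataFrame  # index = gene, columns chrom, start, end

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"position table needs columns {sorted(required)}")
        bad = self.table["start"] > self.table["end"]
        if bad.any():
            raise ValueError(
                f"start > end for genes {list(self.table.index[bad])[:5]}"
            )
        keys = [_chrom_sort_key(c) for c in self.table["chrom"]]
        order = sorted(
            range(len(self.table)),
            key=lambda i: (keys[i], int(self.table["start"].iloc[i]), self.table.index[i]),
        )
        self.table = self.table.iloc[order]

    def ordered_genes(self, universe=None) -> list[str]:
        """Genes in genome order, optionally restricted to ``universe``.

        Genes of ``universe`` absent from the table are returned separately
        (flagged, never silently dropped).
        """
        if universe is None:
            return list(self.table.index)
        uni = set(universe)
        present = [g for g in self.table.index if g in uni]
        missing = sorted(uni - set(self.table.index))
        if missing:
            logger.warning(
                "%d genes have no genomic position and are excluded from "
                "genome ordering (e.g. %s)", len(missing), missing[:5],
            )
        return present

    def chromosome_of(self, genes) -> np.ndarray:
        return self.table.loc[list(genes), "chrom"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_counts_mtx(path: Path) -> pd.DataFrame:
    """MTX triplet, genes x spots, with name sidecars next to the matrix."""
    mat = mmread(path)
    if issparse(mat):
        mat = mat.toarray()
    stem = path.with_suffix("")
    genes_file = Path(f"{stem}.genes.txt")
    barcodes_file = Path(f"{stem}.barcodes.txt")
    for f in (genes_file, barcodes_file):
        if not f.exists():
            raise FileNotFoundError(f"MTX sidecar not found: {f}")
    genes = genes_file.read_text().split()
    barcodes = barcodes_file.read_text().split()
    if mat.shape != (len(genes), len(barcodes)):
        raise SpotDatasetError(
            f"MTX shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    return pd.DataFrame(mat.T, index=barcodes, columns=genes)


def _read_counts_tsv(path: Path, coord_barcodes: set[str]) -> pd.DataFrame:
    """TSV with row/column names; orientation detected against the coords."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col_hits = sum(c in coord_barcodes for c in df.columns)
    row_hits = sum(r in coord_barcodes for r in df.index)
    if col_hits > row_hits:
        df = df.T  # was genes x spots
    return df


def read_spot_dataset(
    counts_path, coords_path, min_counts: int = 1, normalize: bool = True
) -> SpotDataset:
    """Load counts + coordinates into a validated :class:`SpotDataset`.

    Spots with total counts below ``min_counts`` are the "empty" grid
    positions: they are removed from the analysis matrix but their
    coordinates are kept so the neighborhood graph can respect the holes.
    Barcode sets of the two files are reconciled by intersection and the
    number of dropped barcodes is logged.
    """
    counts_path = Path(counts_path)
    coords = pd.read_csv(coords_path, sep="\t")
    required = {"barcode", "x", "y"}
    if not required.issubset(coords.columns):
        raise SpotDatasetError(f"coords file needs columns {sorted(required)}")
    coords = coords.set_index("barcode")

    if counts_path.suffix == ".mtx":
        counts = _read_counts_mtx(counts_path)
    else:
        counts = _read_counts_tsv(counts_path, set(coords.index))

    shared = [b for b in counts.index if b in coords.index]
    if not shared:
        raise SpotDatasetError("no barcode shared between counts and coordinates")
    dropped = len(counts) - len(shared)
    if dropped:
        logger.warning("dropped %d barcodes with counts but no coordinates", dropped)
    # positions listed in the coords file without counts are empty grid holes
    coords_only = coords.index.difference(counts.index)
    hole_coords = coords.loc[coords_only, ["x", "y"]].to_numpy()
    counts = counts.loc[shared]
    coords = coords.loc[shared]

    if (counts.to_numpy() < 0).any():
        raise SpotDatasetError("negative counts")

    totals = counts.sum(axis=1).to_numpy()
    occupied = totals >= min_counts
    n_empty = int((~occupied).sum())
    if n_empty:
        logger.info("%d spots below min_counts=%d marked empty", n_empty, min_counts)
    dataset = SpotDataset(
        counts=counts.to_numpy()[occupied].astype(np.int64),
        coords=coords[["x", "y"]].to_numpy()[occupied],
        barcodes=list(counts.index[occupied]),
        genes=[str(g).strip() for g in counts.columns],
        empty_coords=np.vstack([coords[["x", "y"]].to_numpy()[~occupied], hole_coords]),
    )
    if normalize:
        dataset = tp10k_normalize(dataset)
    return dataset


def write_spot_dataset(dataset: SpotDataset, counts_path, coords_path, fmt: str = "tsv") -> None:
    """Write counts (TSV spots x genes, or MTX genes x spots) plus coords TSV."""
    counts_path = Path(counts_path)
    if fmt == "tsv":
        pd.DataFrame(
            dataset.counts, index=dataset.barcodes, columns=dataset.genes
        ).to_csv(counts_path, sep="\t")
    elif fmt == "mtx":
        mmwrite(str(counts_path), coo_matrix(dataset.counts.T))
        stem = counts_path.with_suffix("")
        Path(f"{stem}.genes.txt").write_text("\n".join(dataset.genes) + "\n")
        Path(f"{stem}.barcodes.txt").write_text("\n".join(dataset.barcodes) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    all_coords = np.vstack([dataset.coords, dataset.empty_coords])
    names = dataset.barcodes + [
        f"EMPTY_{i}" for i in range(len(dataset.empty_coords))
    ]
    pd.DataFrame(
        {"barcode": names, "x": all_coords[:, 0], "y": all_coords[:, 1]}
    ).to_csv(coords_path, sep="\t", index=False)


def tp10k_normalize(dataset: SpotDataset, log1p: bool = False) -> SpotDataset:
    """Rescale each spot to 10,000 total counts (TP10K).

    Raw counts are retained unchanged; the result is stored in
    ``dataset.normalized``.  With ``log1p=True`` the stored matrix is
    ``log1p`` of the TP10K values (off by default — downstream scoring is
    defined on the linear TP10K scale).
    """
    totals = dataset.total_counts().astype(float)
    if np.any(totals <= 0):
        raise SpotDatasetError(
            "occupied spot with zero total counts — should have been marked empty"
        )
    norm = dataset.counts * (10_000.0 / totals[:, None])
    if log1p:
        norm = np.log1p(norm)
    dataset.normalized = norm
    return dataset


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, tab-separated genes)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0].strip()
            genes: list[str] = []
            seen = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    logger.warning("GMT line %d: duplicate gene %s in %s", lineno, g, name)
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_marker_table(path) -> MarkerSet:
    """Two-column TSV (cell_type, gene); a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.empty:
        raise ValueError("empty marker table")
    if list(df.iloc[0].str.lower())[:2] == ["cell_type", "gene"]:
        df = df.iloc[1:]
    markers: dict[str, list[str]] = {}
    for ct, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        markers.setdefault(ct.strip(), []).append(gene.strip())
    return MarkerSet(markers)


def write_marker_table(markers: MarkerSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_type\tgene\n")
        for ct, genes in markers:
            for g in genes:
                fh.write(f"{ct}\t{g}\n")


def read_gene_positions(path) -> GenePositionTable:
    """BED-like 4-column TSV: gene, chromosome, start, end."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["gene", "chrom", "start", "end"],
        dtype={"gene": str, "chrom": str},
    )
    if df.empty:
        raise ValueError("empty gene position table")
    df["gene"] = df["gene"].str.strip()
    df = df.set_index("gene")
    return GenePositionTable(df)


def write_gene_positions(positions: GenePositionTable, path) -> None:
    positions.table.reset_index().to_csv(path, sep="\t", header=False, index=False)
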