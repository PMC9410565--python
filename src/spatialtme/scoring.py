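"""Per-spot cell-type abundance and pathway activity scores.

Cell-type abundance is the mean TP10K expression of the cell type's marker
genes at each spot.  Pathway activity is a ranking-based recovery-curve AUC:
per spot, all genes are ranked by decreasing expression (ties broken by a
seeded random permutation applied before ranking), and the score is the area
under the step curve counting gene-set members among the top ``top_frac``
of the ranking, normalized by the area of a perfect ranking — so scores lie
in [0, 1], with 1 meaning every set gene sits at the very top.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection, MarkerSet, SpotDataset

logger = logging.getLogger(__name__)

__all__ = ["ScoreTable", "cell_type_scores", "pathway_scores"]


@dataclass
class ScoreTable:
    """Spot x feature score matrix with provenance of how it was computed."""

    values: pd.DataFrame  # index = barcodes, columns = features
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("feature names are not unique")
        if self.values.isna().any().any():
            raise ValueError("missing score values")

    @property
    def barcodes(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def vector(self, feature: str) -> np.ndarray:
        return self.values[feature].to_numpy(dtype=float)

    def write(self, path, sidecar: bool = True) -> None:
        self.values.to_csv(path, sep="\t")
        if sidecar:
            with open(f"{path}.json", "w") as fh:
                json.dump(self.provenance, fh, indent=2, default=str)


def cell_type_scores(dataset: SpotDataset, markers: MarkerSet) -> ScoreTable:
    """Mean normalized expression of each type's markers per spot.

    Markers absent from the gene universe are excluded (and logged); a cell
    type with no marker present at all is an error.
    """
    if dataset.normalized is None:
        raise ValueError("dataset is not normalized; run tp10k_normalize first")
    cols = {}
    for ct, genes in markers:
        idx = dataset.gene_index(genes)
        missing = len(genes) - len(idx)
        if missing:
            logger.warning(
                "cell type %s: %d of %d markers absent from the matrix",
                ct, missing, len(genes),
            )
        if len(idx) == 0:
            raise ValueError(f"cell type {ct!r} has no marker present in the matrix")
        cols[ct] = dataset.normalized[:, idx].mean(axis=1)
    return ScoreTable(
        values=pd.DataFrame(cols, index=dataset.barcodes),
        provenance={
            "method": "marker_mean",
            "matrix": "tp10k",
            "n_markers_used": {ct: int(len(dataset.gene_index(g))) for ct, g in markers},
        },
    )


def _rank_matrix(expr: np.ndarray, seed: int) -> np.ndarray:
    """1-based rank of every gene per spot, decreasing expression.

    Ties are broken by one seeded random permutation of the gene order,
    applied before ranking, so equal values receive a reproducible random
    relative order that is shared across spots.
    """
    n_spots, n_genes = expr.shape
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_genes)
    ranks = np.empty((n_spots, n_genes), dtype=np.int64)
    shuffled = expr[:, perm]
    for s in range(n_spots):
        # stable sort on the permuted columns = random tie order
        order = np.argsort(-shuffled[s], kind="stable")
        ranks[s, perm[order]] = np.arange(1, n_genes + 1)
    return ranks


def pathway_scores(
    dataset: SpotDataset,
    genesets: GeneSetCollection,
    top_frac: float = 0.05,
    seed: int = 0,
) -> ScoreTable:
    """Recovery-curve AUC enrichment of each gene set per spot.

    With maxRank = ceil(top_frac * n_genes) and hits(r) the number of set
    genes at rank <= r, the raw AUC is sum of hits(r) for r = 1..maxRank
    (rectangle integration of the right-continuous step curve) and the score
    is raw AUC divided by the AUC of a perfect ranking,
    sum of min(r, |set in universe|).
    """
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must lie strictly between 0 and 1")
    if dataset.normalized is None:
        raise ValueError("dataset is not normalized; run tp10k_normalize first")
    n_genes = dataset.n_genes
    max_rank = int(np.ceil(top_frac * n_genes))
    ranks = _rank_matrix(dataset.normalized, seed=seed)

    cols = {}
    for name, genes in genesets:
        idx = dataset.gene_index(genes)
        if len(idx) == 0:
            logger.warning("gene set %s has no gene in the universe; dropped", name)
            continue
        set_ranks = ranks[:, idx]  # spots x set genes
        contrib = np.clip(max_rank - set_ranks + 1, 0, None)
        raw_auc = contrib.sum(axis=1)
        r = np.arange(1, max_rank + 1)
        max_auc = np.minimum(r, len(idx)).sum()
        cols[name] = raw_auc / max_auc
    if not cols:
        raise ValueError("no gene set has any gene in the universe")
    return ScoreTable(
        values=pd.DataFrame(cols, index=dataset.barcodes),
        provenance={
            "method": "auc_recovery",
            "matrix": "tp10k",
            "top_frac": top_frac,
            "max_rank": max_rank,
            "seed": seed,
        },
    )
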