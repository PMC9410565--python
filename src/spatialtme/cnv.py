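"""Expression-based copy-number profiles and spatial subclone maps.

Large copy-number events leave a coordinated shift in expression across
contiguous stretches of the genome.  The profile here follows the classic
denoising recipe: log-transform normalized expression, subtract the
per-gene mean of a reference (non-malignant) spot set, order genes along
the genome, smooth with a centered moving average within each chromosome,
re-center each spot at its median, and clip extreme values.  Tumor-rich
spots are then clustered on their smoothed profiles (Ward linkage on
Euclidean distances) into 2-4 subclones, with the number of clones chosen
by mean silhouette, and the labels mapped back onto the array coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .io import GenePositionTable, SpotDataset
from .scoring import ScoreTable

logger = logging.getLogger(__name__)

__all__ = ["SubcloneMap", "cnv_profile", "cluster_subclones"]


@dataclass
class SubcloneMap:
    """Subclone labels over the array, plus the clustering that produced them.

    ``labels`` holds an integer clone id (1..k) for every tumor-rich spot and
    0 for reference-side spots.
    """

    labels: pd.Series                  # index = all barcodes; 0 = reference side
    k: int
    linkage_matrix: np.ndarray         # Ward tree over the tumor-rich spots
    tumor_spots: list[str]
    coords: pd.DataFrame               # barcode-indexed x, y
    silhouette_by_k: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        out = self.coords.copy()
        out["subclone"] = self.labels
        return out


def _smooth_within_chromosomes(
    values: np.ndarray, chroms: np.ndarray, window: int
) -> np.ndarray:
    """Centered moving average of length ``window`` within each chromosome.

    Edge windows are truncated: each position is averaged over the window
    positions that exist on its chromosome.
    """
    if window == 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        block = values[:, cols]
        m = len(cols)
        csum = np.concatenate(
            [np.zeros((values.shape[0], 1)), np.cumsum(block, axis=1)], axis=1
        )
        starts = np.maximum(np.arange(m) - half, 0)
        stops = np.minimum(np.arange(m) + half + 1, m)
        out[:, cols] = (csum[:, stops] - csum[:, starts]) / (stops - starts)
    return out


def cnv_profile(
    dataset: SpotDataset,
    positions: GenePositionTable,
    reference_spots: list[str],
    window: int = 101,
    clip: float = 1.0,
    min_expr_frac: float = 0.05,
) -> pd.DataFrame:
    """Smoothed relative copy-number profile per spot (log2 scale, clipped).

    Steps per spot: log2(TP10K + 1); subtract the per-gene mean over
    ``reference_spots``; order genes by genome position; centered moving
    average of ``window`` genes within each chromosome (truncated at
    chromosome edges); subtract the per-spot median; clip to [-clip, clip].
    Genes without a genomic position or expressed in fewer than
    ``min_expr_frac`` of spots are excluded.
    """
    if dataset.normalized is None:
        raise ValueError("dataset is not normalized; run tp10k_normalize first")
    if len(reference_spots) == 0:
        raise ValueError("empty reference spot set")
    ref_idx = [dataset.barcodes.index(b) for b in reference_spots]

    expressed = (dataset.counts > 0).mean(axis=0) >= min_expr_frac
    universe = [g for g, keep in zip(dataset.genes, expressed) if keep]
    ordered = positions.ordered_genes(universe)
    if not ordered:
        raise ValueError("no expressed gene has a genomic position")
    gidx = dataset.gene_index(ordered)
    chroms = positions.chromosome_of(ordered)
    counts_per_chrom = pd.Series(chroms).value_counts()
    if (counts_per_chrom < window / 4).all():
        raise ValueError(
            f"every chromosome has fewer than window/4 = {window / 4:.0f} genes; "
            "smoothing would be meaningless"
        )

    logexpr = np.log2(dataset.normalized[:, gidx] + 1.0)
    centered = logexpr - logexpr[ref_idx].mean(axis=0)
    smoothed = _smooth_within_chromosomes(centered, chroms, window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    np.clip(smoothed, -clip, clip, out=smoothed)
    return pd.DataFrame(smoothed, index=dataset.barcodes, columns=ordered)


def cluster_subclones(
    cnv: pd.DataFrame,
    tumor_scores: ScoreTable,
    tumor_feature: str = "tumor",
    k_range: tuple[int, int] = (2, 4),
    tumor_quantile: float = 0.5,
    coords: pd.DataFrame | None = None,
) -> SubcloneMap:
    """Cluster tumor-rich spots into K subclones on their CNV profiles.

    Tumor-rich spots are those whose tumor abundance score exceeds the given
    quantile of the score distribution.  Ward-linkage hierarchical clustering
    on Euclidean distances between smoothed CNV rows; K is chosen within
    ``k_range`` by maximum mean silhouette.  Identical profiles (silhouette
    undefined) fall back to the smallest K with a warning.
    """
    k_lo, k_hi = k_range
    if not 2 <= k_lo <= k_hi:
        raise ValueError(f"invalid k_range {k_range}")
    score = tumor_scores.values[tumor_feature]
    threshold = score.quantile(tumor_quantile)
    tumor_spots = [b for b in cnv.index if score.loc[b] > threshold]
    if len(tumor_spots) < 3 * k_lo:
        raise ValueError(
            f"only {len(tumor_spots)} tumor-rich spots; need at least {3 * k_lo}"
        )
    profiles = cnv.loc[tumor_spots].to_numpy()
    Z = linkage(profiles, method="ward", metric="euclidean")

    sil: dict[int, float] = {}
    best_k, best_sil = k_lo, -np.inf
    degenerate = np.allclose(profiles, profiles[0])
    if degenerate:
        logger.warning("identical CNV profiles; silhouette undefined, using K=%d", k_lo)
    else:
        for k in range(k_lo, k_hi + 1):
            labels_k = fcluster(Z, t=k, criterion="maxclust")
            if len(np.unique(labels_k)) < 2:
                continue
            sil[k] = float(silhouette_score(profiles, labels_k))
            if sil[k] > best_sil:
                best_k, best_sil = k, sil[k]
    labels_tumor = fcluster(Z, t=best_k, criterion="maxclust")

    labels = pd.Series(0, index=cnv.index, name="subclone")
    labels.loc[tumor_spots] = labels_tumor
    if coords is None:
        coords = pd.DataFrame(
            {"x": np.nan, "y": np.nan}, index=cnv.index
        )
    return SubcloneMap(
        labels=labels,
        k=int(best_k),
        linkage_matrix=Z,
        tumor_spots=tumor_spots,
        coords=coords.loc[cnv.index],
        silhouette_by_k=sil,
    )
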