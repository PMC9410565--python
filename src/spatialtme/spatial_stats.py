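"""Global spatial autocorrelation and graph-distance semivariograms.

Moran's I over a weight matrix w is

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with W the sum of all weights and w_ii = 0.  Under the permutation null its
expectation is -1/(N-1): positive I means similar values cluster among
neighbors, negative I means alternation.  Inference is by random permutation
of the values over the nodes.

The semivariogram gamma(d) is half the mean squared difference of the
variable over node pairs at graph hop distance exactly d; on a spot array
one hop is one spot pitch (200 um), so the lag axis is in spot units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import NeighborGraph

logger = logging.getLogger(__name__)

__all__ = ["SpatialStatResult", "Variogram", "morans_i", "morans_i_test", "semivariogram"]


@dataclass
class SpatialStatResult:
    """Moran's I with its permutation null."""

    feature: str
    I: float
    expected_i: float
    n_perm: int
    perm_values: np.ndarray
    p_value: float
    weights: str
    alternative: str = "two-sided"

    def to_row(self) -> dict:
        return {
            "feature": self.feature,
            "I": self.I,
            "expected_I": self.expected_i,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "perm_mean": float(np.mean(self.perm_values)),
            "weights": self.weights,
            "alternative": self.alternative,
        }


@dataclass
class Variogram:
    """Empirical semivariance per hop lag, with pair counts."""

    lags: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d": self.lags, "gamma": self.gamma, "n_pairs": self.n_pairs})

    def ratio_to_first_lag(self) -> np.ndarray:
        """gamma(d) / gamma(1) — how much semivariance rises with distance."""
        if len(self.gamma) == 0 or self.gamma[0] == 0:
            return np.full_like(self.gamma, np.nan)
        return self.gamma / self.gamma[0]


def _weight_matrix(graph: NeighborGraph, weights: str):
    if weights == "binary":
        return graph.W_binary
    if weights == "row":
        return graph.W_row
    raise ValueError(f"weights must be 'binary' or 'row', got {weights!r}")


def morans_i(x, graph: NeighborGraph, weights: str = "binary") -> float:
    """Evaluate Moran's I of ``x`` on the graph's weight matrix."""
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n_nodes,):
        raise ValueError(f"x has shape {x.shape}, expected ({graph.n_nodes},)")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("zero variance: Moran's I is undefined for constant x")
    W = _weight_matrix(graph, weights)
    w_total = float(W.sum())
    if w_total == 0.0:
        raise ValueError("graph has no edges")
    num = float(z @ (W @ z))
    return (graph.n_nodes / w_total) * num / denom


def morans_i_test(
    x,
    graph: NeighborGraph,
    n_perm: int = 999,
    seed: int = 0,
    weights: str = "binary",
    feature: str = "feature",
    alternative: str = "two-sided",
) -> SpatialStatResult:
    """Permutation test for Moran's I.

    The observed statistic is compared with ``n_perm`` random relabelings of
    the values over the nodes; the p-value uses the add-one correction
    p = (1 + #extreme) / (n_perm + 1).  Two-sided extremeness is measured as
    distance from the null expectation -1/(N-1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    i_obs = morans_i(x, graph, weights=weights)
    n = graph.n_nodes
    e_i = -1.0 / (n - 1)

    W = _weight_matrix(graph, weights)
    w_total = float(W.sum())
    rng = np.random.default_rng(seed)
    perm_values = np.empty(n_perm)
    z = x - x.mean()
    denom = float(z @ z)
    for k in range(n_perm):
        zp = rng.permutation(z)
        perm_values[k] = (n / w_total) * float(zp @ (W @ zp)) / denom

    if alternative == "two-sided":
        extreme = np.abs(perm_values - e_i) >= abs(i_obs - e_i) - 1e-15
    elif alternative == "greater":
        extreme = perm_values >= i_obs - 1e-15
    else:
        extreme = perm_values <= i_obs + 1e-15
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return SpatialStatResult(
        feature=feature,
        I=i_obs,
        expected_i=e_i,
        n_perm=n_perm,
        perm_values=perm_values,
        p_value=p,
        weights=weights,
        alternative=alternative,
    )


def semivariogram(
    x,
    graph: NeighborGraph,
    d_max: int = 6,
    min_pairs: int = 30,
) -> Variogram:
    """Empirical semivariogram over graph hop distances 1..d_max.

    gamma(d) = (1 / (2 n_pairs(d))) * sum over unordered pairs at hop
    distance exactly d of (x_i - x_j)^2.  Lags with fewer than ``min_pairs``
    pairs are suppressed (pair count reported, gamma set to NaN) to avoid
    noisy tail estimates.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n_nodes,):
        raise ValueError(f"x has shape {x.shape}, expected ({graph.n_nodes},)")
    hop = graph.hop_distances()
    iu = np.triu_indices(graph.n_nodes, k=1)
    d_pair = hop[iu]
    sq = (x[iu[0]] - x[iu[1]]) ** 2

    lags = np.arange(1, d_max + 1)
    gamma = np.full(d_max, np.nan)
    n_pairs = np.zeros(d_max, dtype=int)
    for k, d in enumerate(lags):
        mask = d_pair == d
        n_pairs[k] = int(mask.sum())
        if n_pairs[k] >= min_pairs:
            gamma[k] = sq[mask].sum() / (2.0 * n_pairs[k])
    if (n_pairs == 0).all():
        logger.warning("no node pair at any lag <= %d", d_max)
    return Variogram(lags=lags, gamma=gamma, n_pairs=n_pairs)
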