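"""Spatial PCA and spatial-lag autoregressive regression.

Spatial PCA (sPCA) eigendecomposes the symmetric spatially lagged covariance

    Omega = (1 / 2n) X^T (W + W^T) X

of the centered (optionally scaled) score matrix X, with W row-standardized.
Each eigenvalue factors exactly as lambda_k = var(score_k) * I(score_k):
large positive eigenvalues are globally smooth (spatially clustered)
structure, large negative eigenvalues are local contrast structure.

The spatial-lag model

    y = rho * W y + X beta + eps,   eps ~ N(0, sigma^2 I)

is fit by maximum likelihood using the concentrated log-likelihood: for a
candidate rho, beta and sigma^2 have closed forms, and the Jacobian term
log|I - rho W| is a sum of log(1 - rho * lambda_i) over the eigenvalues of
W.  rho ("Rho") measures how strongly a spot's response depends on its
neighbors' responses; its feasible interval is (1/lambda_min, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .graph import NeighborGraph
from .scoring import ScoreTable
from .spatial_stats import morans_i

logger = logging.getLogger(__name__)

__all__ = ["SPCAResult", "LagModelFit", "spca", "lag_model_fit", "fit_all_pathways"]


# ---------------------------------------------------------------------------
# spatial PCA
# ---------------------------------------------------------------------------

@dataclass
class SPCAResult:
    eigenvalues: np.ndarray            # descending, signed
    loadings: pd.DataFrame             # features x components, unit-norm columns
    scores: pd.DataFrame               # spots x components
    variance_part: np.ndarray          # var(score_k)
    moran_part: np.ndarray             # I(score_k), row-standardized weights
    scaled: bool = True
    dropped_features: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def spca(scores: ScoreTable, graph: NeighborGraph, scale: bool = True) -> SPCAResult:
    """Spatial PCA of a score table on the neighborhood graph.

    Features with zero variance are dropped with a warning; at least two
    must remain.  Loadings are unit-norm eigenvectors of Omega, component
    scores are X @ loadings, and the eigenvalue identity
    lambda_k = var(score_k) * I(score_k) holds with row-standardized weights.
    """
    if scores.barcodes != graph.nodes:
        raise ValueError("score table and graph are not aligned on the same spots")
    X = scores.values.to_numpy(dtype=float)
    names = list(scores.values.columns)
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("dropping zero-variance features: %s", dropped)
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 features with nonzero variance")

    n = X.shape[0]
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0)
    W = graph.W_row.toarray()
    omega = X.T @ ((W + W.T) @ X) / (2.0 * n)
    omega = (omega + omega.T) / 2.0
    evals, evecs = np.linalg.eigh(omega)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    comp_scores = X @ evecs

    var_part = comp_scores.var(axis=0)
    moran_part = np.array(
        [morans_i(comp_scores[:, k], graph, weights="row") for k in range(len(evals))]
    )
    comp_names = [f"sPC{k + 1}" for k in range(len(evals))]
    return SPCAResult(
        eigenvalues=evals,
        loadings=pd.DataFrame(evecs, index=names, columns=comp_names),
        scores=pd.DataFrame(comp_scores, index=scores.barcodes, columns=comp_names),
        variance_part=var_part,
        moran_part=moran_part,
        scaled=scale,
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# spatial-lag regression
# ---------------------------------------------------------------------------

@dataclass
class LagModelFit:
    response: str
    rho: float
    beta: pd.Series
    se: pd.Series                      # index: ["rho", *beta names]
    z: pd.Series
    p: pd.Series
    sigma2: float
    loglik: float
    loglik_rho0: float
    rho_interval: tuple[float, float]
    boundary_warning: bool = False

    def coefficient_frame(self) -> pd.DataFrame:
        terms = ["rho", *self.beta.index]
        est = pd.Series([self.rho, *self.beta.to_numpy()], index=terms)
        return pd.DataFrame(
            {
                "estimate": est,
                "se": self.se.reindex(terms),
                "z": self.z.reindex(terms),
                "p": self.p.reindex(terms),
            }
        )


def row_weight_eigenvalues(graph: NeighborGraph) -> np.ndarray:
    """Real eigenvalues of the row-standardized weight matrix.

    For a symmetric binary adjacency, D^-1 A is similar to the symmetric
    D^-1/2 A D^-1/2, so the spectrum is real and computable with a symmetric
    solver; isolated nodes contribute zero eigenvalues.
    """
    deg = graph.degrees.astype(float)
    nz = deg > 0
    lam = np.zeros(graph.n_nodes)
    if nz.any():
        A = graph.W_binary.toarray()[np.ix_(nz, nz)]
        s = 1.0 / np.sqrt(deg[nz])
        M = A * np.outer(s, s)
        lam[: nz.sum()] = np.linalg.eigvalsh(M)
    return np.sort(lam)


def _design_checks(X: np.ndarray, names: list[str]) -> None:
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, pivoting=True, mode="economic")
        tol = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[k]] for k in range(X.shape[1]) if abs(R[k, k]) < tol]
        raise ValueError(f"singular design: collinear columns {bad}")


def lag_model_fit(
    y,
    X,
    graph: NeighborGraph,
    response: str = "y",
    feature_names: list[str] | None = None,
    min_component_fraction: float = 0.9,
) -> LagModelFit:
    """Fit y = rho W y + X beta + eps by concentrated maximum likelihood.

    ``X`` must already contain the intercept column.  Standard errors come
    from the inverse negative numerical Hessian of the full log-likelihood
    in (rho, beta, sigma^2) at the optimum; per-coefficient p-values are
    two-sided Wald.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{k}" for k in range(p)]
    if y.shape != (n,) or n != graph.n_nodes:
        raise ValueError("y, X and graph sizes disagree")
    if n <= p + 2:
        raise ValueError(f"too few observations (n={n}) for {p} predictors")
    if np.var(y) == 0:
        raise ValueError("zero variance: constant response")
    frac = graph.largest_component_fraction()
    if frac < min_component_fraction:
        raise ValueError(
            f"largest graph component holds {frac:.0%} of nodes "
            f"(< {min_component_fraction:.0%}); rho is not comparable on "
            "fragmented graphs"
        )
    _design_checks(X, feature_names)

    lam = row_weight_eigenvalues(graph)
    lam_min, lam_max = lam.min(), lam.max()
    lo = 1.0 / lam_min if lam_min < 0 else -np.inf
    hi = 1.0 / lam_max if lam_max > 0 else np.inf
    lo, hi = max(lo, -1e6) + 1e-8, min(hi, 1e6) - 1e-8

    W = graph.W_row
    Wy = W @ y
    xtx = X.T @ X
    log_jac = lambda rho: float(np.log1p(-rho * lam).sum())

    def profile(rho: float):
        ay = y - rho * Wy
        beta = np.linalg.solve(xtx, X.T @ ay)
        resid = ay - X @ beta
        sigma2 = float(resid @ resid) / n
        return beta, sigma2

    def cll(rho: float) -> float:
        _, sigma2 = profile(rho)
        return -(n / 2.0) * (np.log(2 * np.pi * sigma2) + 1.0) + log_jac(rho)

    opt = minimize_scalar(
        lambda r: -cll(r), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    rho_hat = float(opt.x)
    boundary = min(rho_hat - lo, hi - rho_hat) < 1e-6
    if boundary:
        logger.warning("rho estimate %.6f is at the feasible boundary", rho_hat)
    beta_hat, sigma2_hat = profile(rho_hat)
    loglik = cll(rho_hat)
    loglik0 = cll(0.0) if lo < 0.0 < hi else -np.inf

    # full log-likelihood for the observed-information standard errors
    def full_ll(theta: np.ndarray) -> float:
        rho, beta, sigma2 = theta[0], theta[1 : 1 + p], theta[1 + p]
        if sigma2 <= 0 or not (lo < rho < hi):
            return -np.inf
        resid = y - rho * Wy - X @ beta
        return (
            -(n / 2.0) * np.log(2 * np.pi * sigma2)
            - float(resid @ resid) / (2.0 * sigma2)
            + log_jac(rho)
        )

    theta = np.concatenate([[rho_hat], beta_hat, [sigma2_hat]])
    H = _numerical_hessian(full_ll, theta)
    se = np.full(len(theta), np.nan)
    try:
        cov = np.linalg.inv(-H)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        logger.warning("Hessian not invertible; standard errors unavailable")

    terms = ["rho", *feature_names]
    est = np.concatenate([[rho_hat], beta_hat])
    se_s = pd.Series(se[: 1 + p], index=terms)
    z = pd.Series(est, index=terms) / se_s
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LagModelFit(
        response=response,
        rho=rho_hat,
        beta=pd.Series(beta_hat, index=feature_names),
        se=se_s,
        z=z,
        p=pd.Series(pvals, index=terms),
        sigma2=sigma2_hat,
        loglik=loglik,
        loglik_rho0=loglik0,
        rho_interval=(float(lo), float(hi)),
        boundary_warning=bool(boundary),
    )


def _numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = len(theta)
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h[i]
                tm[i] -= h[i]
                H[i, i] = (f(tp) - 2.0 * f(theta) + f(tm)) / h[i] ** 2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[[i, j]] += [h[i], h[j]]
                tpm[i] += h[i]
                tpm[j] -= h[j]
                tmp[i] -= h[i]
                tmp[j] += h[j]
                tmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (
                    4.0 * h[i] * h[j]
                )
    return H


def fit_all_pathways(
    pathways: ScoreTable,
    celltypes: ScoreTable,
    graph: NeighborGraph,
) -> tuple[dict[str, LagModelFit], pd.DataFrame]:
    """One spatial-lag fit per pathway with standardized cell-type predictors.

    Returns the per-pathway fits and a long-format coefficient table with
    Wald p-values and a Benjamini-Hochberg adjusted column (computed over
    all cell-type coefficients, intercept and rho excluded).  Failed fits
    are recorded, not fatal to the batch.
    """
    if pathways.barcodes != celltypes.barcodes:
        raise ValueError("pathway and cell-type tables are not on the same spots")
    ct = celltypes.values.to_numpy(dtype=float)
    ct_sd = ct.std(axis=0)
    if (ct_sd == 0).any():
        bad = [c for c, s in zip(celltypes.features, ct_sd) if s == 0]
        raise ValueError(f"constant cell-type scores: {bad}")
    ct_std = (ct - ct.mean(axis=0)) / ct_sd
    X = np.column_stack([np.ones(ct.shape[0]), ct_std])
    names = ["intercept", *celltypes.features]

    fits: dict[str, LagModelFit] = {}
    rows = []
    for pw in pathways.features:
        try:
            fit = lag_model_fit(
                pathways.vector(pw), X, graph, response=pw, feature_names=names
            )
        except ValueError as exc:
            logger.warning("fit failed for pathway %s: %s", pw, exc)
            rows.append({"pathway": pw, "term": "ERROR", "estimate": np.nan,
                         "se": np.nan, "z": np.nan, "p": np.nan,
                         "rho": np.nan, "sigma2": np.nan, "note": str(exc)})
            continue
        fits[pw] = fit
        frame = fit.coefficient_frame().reset_index(names="term")
        frame.insert(0, "pathway", pw)
        frame["rho"] = fit.rho
        frame["sigma2"] = fit.sigma2
        frame["note"] = ""
        rows.append(frame)
    long = pd.concat(
        [r if isinstance(r, pd.DataFrame) else pd.DataFrame([r]) for r in rows],
        ignore_index=True,
    )
    mask = ~long["term"].isin(["rho", "intercept", "ERROR"]) & long["p"].notna()
    long["p_bh"] = np.nan
    if mask.any():
        long.loc[mask, "p_bh"] = multipletests(long.loc[mask, "p"], method="fdr_bh")[1]
    return fits, long


def pvalue_matrix(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long coefficient table into the pathway x cell-type p-value map."""
    sub = long[~long["term"].isin(["rho", "intercept", "ERROR"])]
    return sub.pivot(index="pathway", columns="term", values="p")
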