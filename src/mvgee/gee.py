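"""Generalized estimating equations for the stacked Gaussian model.

Solves sum_i D_i' V_i^{-1} (y_i - mu_i) = 0 for the identity-link
Gaussian marginal model under a working within-cluster correlation
(independence, exchangeable, AR-1 or unstructured), alternating exact
Fisher-scoring updates of beta with moment re-estimation of the scale and
the correlation parameters from Pearson residuals. Reports both the
model-based (naive) covariance phi * B^{-1} and the robust sandwich
covariance B^{-1} M B^{-1}, the latter valid under working-correlation
misspecification.

Moment-estimator conventions (the number of regression parameters p is
subtracted in both denominators):

    phi    = sum e_r^2 / (n - p)                      (Pearson chi^2 / df)
    alpha  = sum_i sum_{j<l} e_ij e_il / (phi * (sum_i m_i(m_i-1)/2 - p))

with e the raw residuals; for AR-1 the numerator runs over lag-1 pairs
and the pair count is the lag-1 pair count. The working correlation is
defined over the FULL stacked within-subject vector (all times, all
responses): exchangeable uses one alpha covering serial and
cross-response dependence alike. For AR-1 the lag between two rows is
their visit-index difference; same-visit rows of different responses are
assigned lag 1 (correlation alpha) since lag 0 would force correlation 1.
Exchangeable is the primary supported structure; AR-1 exists for
model-selection comparison. Unstructured requires balanced clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .design import StackedDesign

__all__ = [
    "WorkingCorrelation",
    "GEEFit",
    "fit_gee",
    "estimate_exchangeable_alpha",
    "sandwich_covariance",
    "GEEError",
    "RankDeficientError",
]

logger = logging.getLogger(__name__)

STRUCTURES = ("independence", "exchangeable", "ar1", "unstructured")


class GEEError(RuntimeError):
    """Raised on numerical failure inside the estimating-equation solver."""


class RankDeficientError(GEEError):
    """Design matrix is not full column rank."""


@dataclass
class WorkingCorrelation:
    """Fitted working-correlation structure.

    ``alpha`` holds the scalar parameter for exchangeable/AR-1; ``matrix``
    the estimated correlation matrix for unstructured; independence has
    neither. ``clamped`` records whether the moment estimate had to be
    pulled back into the valid range.
    """

    structure: str
    alpha: float | None = None
    matrix: np.ndarray | None = None
    clamped: bool = False

    @property
    def n_params(self) -> int:
        if self.structure == "independence":
            return 0
        if self.structure in ("exchangeable", "ar1"):
            return 1
        m = 0 if self.matrix is None else self.matrix.shape[0]
        return m * (m - 1) // 2


@dataclass
class GEEFit:
    """Result of a GEE fit: coefficients, covariances, convergence record."""

    params: pd.Series
    cov_naive: pd.DataFrame
    cov_robust: pd.DataFrame
    scale: float
    working: WorkingCorrelation
    n_clusters: int
    n_obs: int
    iterations: int
    converged: bool
    max_rel_change: float
    design: StackedDesign = field(repr=False)

    @property
    def se_robust(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_robust.to_numpy())), index=self.params.index
        )

    @property
    def se_naive(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_naive.to_numpy())), index=self.params.index
        )

    def fitted_values(self) -> np.ndarray:
        return self.design.X @ self.params.to_numpy()

    def residuals(self) -> np.ndarray:
        return self.design.y - self.fitted_values()


# ---------------------------------------------------------------------------
# correlation-parameter moment estimators
# ---------------------------------------------------------------------------

def estimate_exchangeable_alpha(
    residuals: np.ndarray,
    cluster_slices: list[slice],
    scale: float,
    n_params: int,
) -> tuple[float, bool]:
    """Moment estimate of the exchangeable correlation.

    alpha = sum_i sum_{j<l} e_ij e_il / (phi * (sum_i m_i (m_i - 1)/2 - p)),
    clamped (with a warning) into the range keeping every observed cluster's
    correlation matrix positive definite. Returns ``(alpha, clamped)``.
    """
    num = 0.0
    pairs = 0.0
    m_max = 1
    for sl in cluster_slices:
        e = residuals[sl]
        m = len(e)
        m_max = max(m_max, m)
        if m < 2:
            continue
        num += (e.sum() ** 2 - (e**2).sum()) / 2.0
        pairs += m * (m - 1) / 2.0
    if pairs == 0:
        raise GEEError(
            "all clusters have a single observation; use the independence "
            "structure instead of exchangeable"
        )
    denom = scale * (pairs - n_params)
    if denom <= 0:
        denom = scale * pairs
    alpha = num / denom
    lo = -1.0 / (m_max - 1) + 1e-6 if m_max > 1 else -1 + 1e-6
    hi = 1.0 - 1e-6
    clamped = not (lo <= alpha <= hi)
    if clamped:
        warnings.warn(
            f"exchangeable alpha estimate {alpha:.4f} outside ({lo:.4f}, {hi:.4f}); "
            "clamped",
            stacklevel=2,
        )
        alpha = min(max(alpha, lo), hi)
    return float(alpha), clamped


def _estimate_ar1_alpha(
    residuals: np.ndarray,
    cluster_slices: list[slice],
    visit_index: np.ndarray,
    scale: float,
    n_params: int,
) -> tuple[float, bool]:
    """Moment estimate of the AR-1 parameter from effective-lag-1 pairs."""
    num = 0.0
    pairs = 0.0
    for sl in cluster_slices:
        e = residuals[sl]
        v = visit_index[sl]
        m = len(e)
        if m < 2:
            continue
        lag = np.abs(v[:, None] - v[None, :])
        iu = np.triu_indices(m, k=1)
        lag1 = lag[iu] <= 1  # adjacent visits and same-visit cross-response
        num += float(np.sum(e[iu[0]][lag1] * e[iu[1]][lag1]))
        pairs += float(lag1.sum())
    if pairs == 0:
        raise GEEError("no lag-1 pairs; AR-1 structure is not identifiable")
    denom = scale * (pairs - n_params)
    if denom <= 0:
        denom = scale * pairs
    alpha = num / denom
    clamped = not (-1 + 1e-6 <= alpha <= 1 - 1e-6)
    if clamped:
        warnings.warn(f"AR-1 alpha estimate {alpha:.4f} clamped", stacklevel=2)
        alpha = min(max(alpha, -1 + 1e-6), 1 - 1e-6)
    return float(alpha), clamped


def _estimate_unstructured(
    residuals: np.ndarray,
    cluster_slices: list[slice],
    visit_index: np.ndarray,
    response_index: np.ndarray,
    scale: float,
    n_params: int,
) -> np.ndarray:
    """Moment estimate of a full correlation matrix (balanced clusters)."""
    pattern = None
    for sl in cluster_slices:
        pat = list(zip(visit_index[sl].tolist(), response_index[sl].tolist()))
        if pattern is None:
            pattern = pat
        elif pat != pattern:
            raise GEEError(
                "unstructured working correlation requires balanced clusters "
                "(identical visit/response patterns); found differing patterns"
            )
    m = len(pattern)
    S = np.zeros((m, m))
    for sl in cluster_slices:
        e = residuals[sl]
        S += np.outer(e, e)
    N = len(cluster_slices)
    denom = scale * max(N - n_params, 1)
    R = S / denom
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    w = np.linalg.eigvalsh(R)[0]
    if w < 1e-6:
        delta = 1e-6 - w
        warnings.warn(
            "unstructured correlation estimate not positive definite; "
            f"shrunk toward identity by {delta:.2e}",
            stacklevel=2,
        )
        R = (R + delta * np.eye(m)) / (1.0 + delta)
    return R


# ---------------------------------------------------------------------------
# working-correlation inverse actions
# ---------------------------------------------------------------------------

def _solve_exchangeable(alpha: float, M: np.ndarray) -> np.ndarray:
    """R^{-1} M for exchangeable R, via the Sherman-Morrison closed form."""
    m = M.shape[0]
    if m == 1 or alpha == 0.0:
        return M
    c = alpha / ((1.0 - alpha) * (1.0 + alpha * (m - 1)))
    return M / (1.0 - alpha) - c * M.sum(axis=0, keepdims=True)


def _corr_matrix(
    work: WorkingCorrelation, v: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """Explicit working correlation matrix for one cluster's rows."""
    m = len(v)
    if work.structure == "independence":
        return np.eye(m)
    if work.structure == "exchangeable":
        R = np.full((m, m), work.alpha)
        np.fill_diagonal(R, 1.0)
        return R
    if work.structure == "ar1":
        lag = np.abs(v[:, None] - v[None, :]).astype(float)
        off = ~np.eye(m, dtype=bool)
        lag[off & (lag == 0)] = 1.0  # same-visit cross-response pairs
        return work.alpha ** lag
    return work.matrix.copy()


def _cluster_solve(
    work: WorkingCorrelation, v: np.ndarray, r: np.ndarray, M: np.ndarray
) -> np.ndarray:
    """Compute R^{-1} M for one cluster under the working structure."""
    if work.structure == "independence" or M.shape[0] == 1:
        return M
    if work.structure == "exchangeable":
        return _solve_exchangeable(work.alpha, M)
    R = _corr_matrix(work, v, r)
    try:
        return np.linalg.solve(R, M)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise GEEError(f"singular working correlation in a cluster: {exc}") from exc


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    _, Rq, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        collinear = [columns[i] for i in piv[rank:]]
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear column(s): {collinear}"
        )


def _update_working(
    work: WorkingCorrelation,
    resid: np.ndarray,
    slices: list[slice],
    design: StackedDesign,
    scale: float,
    p: int,
) -> WorkingCorrelation:
    if work.structure == "independence":
        return work
    if work.structure == "exchangeable":
        alpha, clamped = estimate_exchangeable_alpha(resid, slices, scale, p)
        return WorkingCorrelation("exchangeable", alpha=alpha, clamped=clamped)
    if work.structure == "ar1":
        alpha, clamped = _estimate_ar1_alpha(
            resid, slices, design.visit_index, scale, p
        )
        return WorkingCorrelation("ar1", alpha=alpha, clamped=clamped)
    R = _estimate_unstructured(
        resid, slices, design.visit_index, design.response_index, scale, p
    )
    return WorkingCorrelation("unstructured", matrix=R)


def fit_gee(
    design: StackedDesign,
    corstr: str = "exchangeable",
    tol: float = 1e-8,
    max_iter: int = 100,
    fixed_alpha: float | None = None,
) -> GEEFit:
    """Fit the identity-link Gaussian GEE under a working correlation.

    Parameters
    ----------
    design : StackedDesign
        Stacked response vector and design matrix, rows grouped by cluster.
    corstr : str
        One of ``independence, exchangeable, ar1, unstructured``.
    tol : float
        Convergence threshold on the maximum relative coefficient change.
    max_iter : int
        Iteration cap; non-convergence returns ``converged=False`` with
        diagnostics rather than raising.
    fixed_alpha : float, optional
        Hold the exchangeable/AR-1 parameter fixed instead of estimating
        it (used by oracle cross-checks).

    Notes
    -----
    With the identity link each beta update solves the weighted normal
    equations exactly, so iteration is only needed to let the scale and
    correlation estimates settle. Clusters of size 1 contribute
    independence-like terms. The scale is Pearson chi^2 / (n - p).
    """
    if corstr not in STRUCTURES:
        raise GEEError(f"unknown working correlation structure {corstr!r}")
    X, y = design.X, design.y
    n, p = X.shape
    if n == 0:
        raise GEEError("empty design")
    slices = design.cluster_slices()
    if len(slices) < 2:
        raise GEEError("at least 2 clusters are required")
    _check_rank(X, design.columns)

    # initial fit: independence (= OLS for the identity-link Gaussian)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    scale = float(resid @ resid / (n - p))
    work = WorkingCorrelation(corstr, alpha=0.0 if corstr in ("exchangeable", "ar1") else None)
    # with no within-cluster pairs every structure degenerates to independence:
    # keep the requested label but pin the (unidentifiable) parameter at 0
    no_pairs = all(sl.stop - sl.start < 2 for sl in slices)
    if no_pairs and corstr in ("exchangeable", "ar1") and fixed_alpha is None:
        fixed_alpha = 0.0
    if no_pairs and corstr == "unstructured":
        raise GEEError(
            "unstructured correlation is not identifiable with all clusters "
            "of size 1; use independence"
        )

    converged = False
    max_rel = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        if fixed_alpha is not None and corstr in ("exchangeable", "ar1"):
            work = WorkingCorrelation(corstr, alpha=float(fixed_alpha))
        else:
            work = _update_working(work, resid, slices, design, scale, p)

        B = np.zeros((p, p))
        u = np.zeros(p)
        for sl in slices:
            Xi = X[sl]
            RiX = _cluster_solve(work, design.visit_index[sl],
                                 design.response_index[sl], Xi)
            B += Xi.T @ RiX
            u += RiX.T @ y[sl]
        try:
            beta_new = np.linalg.solve(B, u)
        except np.linalg.LinAlgError as exc:
            raise GEEError(f"singular weighted information matrix: {exc}") from exc

        denom = np.maximum(np.abs(beta), 1.0)
        max_rel = float(np.max(np.abs(beta_new - beta) / denom))
        logger.debug("gee iteration %d: max relative change %.3e", it, max_rel)
        beta = beta_new
        resid = y - X @ beta
        scale = float(resid @ resid / (n - p))
        if max_rel < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"GEE did not converge in {max_iter} iterations "
            f"(last max relative change {max_rel:.3e})",
            stacklevel=2,
        )

    B_R = np.zeros((p, p))
    M_R = np.zeros((p, p))
    for sl in slices:
        Xi = X[sl]
        vi, ri = design.visit_index[sl], design.response_index[sl]
        RiX = _cluster_solve(work, vi, ri, Xi)
        B_R += Xi.T @ RiX
        g = RiX.T @ resid[sl]
        M_R += np.outer(g, g)
    try:
        B_inv = np.linalg.inv(B_R)
    except np.linalg.LinAlgError as exc:
        raise GEEError(f"singular bread matrix: {exc}") from exc
    cov_naive = scale * B_inv
    cov_robust = B_inv @ M_R @ B_inv
    # symmetrize pure floating-point asymmetry only
    cov_robust = (cov_robust + cov_robust.T) / 2.0
    cov_naive = (cov_naive + cov_naive.T) / 2.0

    idx = pd.Index(design.columns)
    return GEEFit(
        params=pd.Series(beta, index=idx),
        cov_naive=pd.DataFrame(cov_naive, index=idx, columns=idx),
        cov_robust=pd.DataFrame(cov_robust, index=idx, columns=idx),
        scale=scale,
        working=work,
        n_clusters=len(slices),
        n_obs=n,
        iterations=it,
        converged=converged,
        max_rel_change=max_rel,
        design=design,
    )


def sandwich_covariance(
    design: StackedDesign, work: WorkingCorrelation, beta: np.ndarray
) -> np.ndarray:
    """Robust covariance B^{-1} M B^{-1} at given beta and working structure.

    B = sum_i X_i' R_i^{-1} X_i and
    M = sum_i X_i' R_i^{-1} e_i e_i' R_i^{-1} X_i (the scale cancels).
    Exposed for direct use in tests and diagnostics; ``fit_gee`` computes
    the same quantity internally at the solution.
    """
    X, y = design.X, design.y
    p = X.shape[1]
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    resid = y - X @ beta
    for sl in design.cluster_slices():
        Xi = X[sl]
        vi, ri = design.visit_index[sl], design.response_index[sl]
        RiX = _cluster_solve(work, vi, ri, Xi)
        B += Xi.T @ RiX
        g = RiX.T @ resid[sl]
        M += np.outer(g, g)
    B_inv = np.linalg.inv(B)
    V = B_inv @ M @ B_inv
    return (V + V.T) / 2.0
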