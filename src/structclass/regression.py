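"""Least-squares machinery: standardization, MLR, the two-round
iterative refit, and sequential forward stepwise feature selection.

Each structural dimension is fitted independently by ordinary least
squares with an intercept.  The two-round procedure first fits the
clamped training targets, then rebuilds each target from the fitted
value wherever the fit already lands on the class-required side with at
least the margin, and refits; this lets well-predicted domains relax to
their natural score while misfit domains keep pulling toward the
required sign.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = [
    "standardize_fit",
    "standardize_apply",
    "fit_mlr",
    "iterative_fit",
    "forward_select",
]

logger = logging.getLogger(__name__)

RIDGE_LAMBDA = 1e-8


def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and scales (population std; zero-variance scale = 1)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales < 1e-12, 1.0, scales)
    return means, scales


def standardize_apply(X: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - means) / scales


def fit_mlr(X: np.ndarray, t: np.ndarray, ridge_lambda: float = RIDGE_LAMBDA) -> np.ndarray:
    """Least-squares coefficients minimizing ||t - X b||^2.

    Solved by SVD-backed ``lstsq``; a rank-deficient design falls back
    to a small ridge penalty (logged) so the solution stays defined on
    degenerate inputs.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot fit a regression on 0 samples")
    beta, _, rank, _ = np.linalg.lstsq(X, t, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "design is rank-deficient (rank %d < %d columns); "
            "applying ridge fallback lambda=%g", rank, X.shape[1], ridge_lambda,
        )
        gram = X.T @ X + ridge_lambda * np.eye(X.shape[1])
        beta = np.linalg.solve(gram, X.T @ t)
    return beta


def refine_targets(
    fitted: np.ndarray, required_sign: np.ndarray, margin: float
) -> np.ndarray:
    """Round-2 targets: keep the fitted value where it is sign-consistent
    with at least the margin, else pull to required_sign * margin."""
    fitted = np.asarray(fitted, dtype=float)
    required_sign = np.asarray(required_sign, dtype=float)
    ok = (np.sign(fitted) == np.sign(required_sign)) & (np.abs(fitted) >= margin)
    return np.where(ok, fitted, required_sign * margin)


def iterative_fit(
    X: np.ndarray,
    t: np.ndarray,
    required_sign: np.ndarray,
    margin: float = 0.05,
    ridge_lambda: float = RIDGE_LAMBDA,
) -> np.ndarray:
    """Two rounds of least squares with a self-consistent target update."""
    beta1 = fit_mlr(X, t, ridge_lambda)
    t2 = refine_targets(X @ beta1, required_sign, margin)
    return fit_mlr(X, t2, ridge_lambda)


def forward_select(X: np.ndarray, t: np.ndarray, m: int) -> list[int]:
    """Sequential forward stepwise selection of ``m`` feature columns.

    The first feature maximizes |Pearson correlation| with the target;
    each later one minimizes the residual sum of squares of the refit
    model (computed by residualizing the remaining columns against the
    chosen span, which is algebraically the same criterion).  Ties break
    to the lowest column index.  The intercept is implicit: columns and
    target are centred first.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    n, p = X.shape
    if not 0 <= m <= p:
        raise ValueError(f"feature budget m={m} outside [0, {p}]")
    if m == 0:
        return []
    Xw = X - X.mean(axis=0)
    r = t - t.mean()

    norms = np.linalg.norm(Xw, axis=0)
    t_norm = np.linalg.norm(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(Xw.T @ r) / (norms * t_norm)
    corr[(norms < 1e-12) | ~np.isfinite(corr)] = 0.0  # zero-variance -> 0
    if t_norm < 1e-12:
        corr[:] = 0.0

    selected: list[int] = []
    available = np.ones(p, dtype=bool)
    scores = corr.copy()
    for _ in range(m):
        scores_masked = np.where(available, scores, -np.inf)
        j = int(np.argmax(scores_masked))  # argmax takes the lowest tied index
        selected.append(j)
        available[j] = False
        # residualize remaining columns and the target against column j
        qn = np.linalg.norm(Xw[:, j])
        if qn > 1e-12:
            q = Xw[:, j] / qn
            Xw = Xw - np.outer(q, q @ Xw)
            r = r - q * (q @ r)
        if len(selected) == m:
            break
        sq = np.einsum("ij,ij->j", Xw, Xw)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = (Xw.T @ r) ** 2 / sq  # RSS reduction if column added
        scores[(sq < 1e-12) | ~np.isfinite(scores)] = -np.inf
    return selected
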