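"""Hadi forward-search multivariate outlier identification.

A deterministic robust-distance detector: starting from the coordinatewise
median and a scatter built from the least-outlying half of the data, a clean
basic subset is grown one point at a time in order of robust Mahalanobis
distance, re-estimating location and scatter (with a small-sample correction
factor) at each step, until the nearest excluded point lies beyond the
chi-square cutoff at level 1 - alpha/n.  Points outside the final subset are
the flagged outliers.  Used here to screen the (log expenditure, log income)
pairs in robustness fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class OutlierReport:
    flags: np.ndarray          # boolean, per row
    distances: np.ndarray      # robust squared distances at termination
    alpha: float
    iterations: int
    ridge_used: bool = False

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def to_dict(self) -> dict:
        return {
            "n_flagged": self.n_flagged,
            "alpha": self.alpha,
            "iterations": self.iterations,
            "flagged_rows": np.flatnonzero(self.flags).tolist(),
        }


def _sq_distances(X: np.ndarray, center: np.ndarray, scatter: np.ndarray) -> tuple[np.ndarray, bool]:
    """Squared Mahalanobis distances; ridge-perturb a singular scatter."""
    p = X.shape[1]
    ridge = False
    S = scatter
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        S = S + np.eye(p) * (1e-10 * np.trace(S) / p + 1e-300)
        ridge = True
        L = np.linalg.cholesky(S)
    sol = np.linalg.solve(L, (X - center).T)
    return np.einsum("ij,ij->j", sol, sol), ridge


def hadi_outliers(X: np.ndarray, alpha: float = 0.05) -> OutlierReport:
    """Flag multivariate outliers by the Hadi forward-search procedure.

    Parameters
    ----------
    X : (n, p) float array, no missing cells, n > p + 1.
    alpha : significance level of the chi-square(p) stopping cutoff, applied
        at 1 - alpha/n (a Bonferroni-style per-point level, which keeps the
        null flag rate near alpha for the whole sample).

    Deterministic; ties in distance are broken by original row order (stable
    sort).  A singular scatter at any step is perturbed by a ridge of
    1e-10 * trace/p and recorded in the report.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 rows (got n={n}, p={p})")
    if not np.isfinite(X).all():
        raise ValueError("X must not contain missing or non-finite cells")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")

    ridge_any = False
    # (1) initial location/scatter: coordinatewise median, covariance of the
    # h = ceil((n+p+1)/2) points closest to the median
    med = np.median(X, axis=0)
    S0 = (X - med).T @ (X - med) / (n - 1)
    d2, r = _sq_distances(X, med, S0)
    ridge_any |= r
    h = int(np.ceil((n + p + 1) / 2))
    order = np.argsort(d2, kind="stable")
    subset = order[:h]

    # small-sample correction factor for the subset scatter
    def cfactor(m: int) -> float:
        c = 1.0 + (p + 1) / (m - p) + 2.0 / (m - 1 - 3 * p) if m - 1 - 3 * p > 0 else 1.0 + (p + 1) / max(m - p, 1)
        return c

    cutoff = stats.chi2.ppf(1.0 - alpha / n, df=p)
    iterations = 0
    while True:
        iterations += 1
        m = len(subset)
        mean = X[subset].mean(axis=0)
        cov = np.cov(X[subset], rowvar=False, ddof=1) * cfactor(m)
        cov = np.atleast_2d(cov)
        d2, r = _sq_distances(X, mean, cov)
        ridge_any |= r
        order = np.argsort(d2, kind="stable")
        if m >= n:
            flags = np.zeros(n, dtype=bool)
            break
        # smallest distance among currently-excluded points
        excluded = order[m:]
        next_d2 = d2[excluded[0]]
        if next_d2 > cutoff:
            inside = np.zeros(n, dtype=bool)
            inside[order[:m]] = True
            flags = ~inside
            break
        subset = order[: m + 1]

    return OutlierReport(
        flags=flags, distances=d2, alpha=alpha, iterations=iterations, ridge_used=ridge_any
    )
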