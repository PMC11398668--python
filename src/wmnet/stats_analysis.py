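"""Structure-function statistics: rank correlations and ridge regression.

The dependent variable is the log-transformed working-memory duration,
ln(duration + offset); censored trials enter at the delay length.  Features
are z-scored column-wise before the ridge fit so that coefficient magnitudes
|beta| are comparable and can rank feature importance.  The ridge objective is

    (1/n) sum_i (y_i - beta0 - beta^T x_i)^2 + lambda ||beta||_2^2

with an unpenalized intercept; the solution is closed-form.  lambda is chosen
on a logarithmic grid by k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "dip_statistic",
    "dip_test",
    "spearman",
    "log_duration_transform",
    "standardize",
    "ridge_fit",
    "cv_lambda",
    "importance_ranking",
    "impute_undefined",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 25)


@dataclass
class RegressionResult:
    beta: np.ndarray
    beta0: float
    lam: float
    cv_score: float | None
    feature_names: tuple[str, ...]

    def series(self) -> pd.Series:
        return pd.Series(self.beta, index=list(self.feature_names))


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN-safe inputs
    are the caller's concern.  Raises on degenerate (zero rank variance)
    input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def log_duration_transform(durations, offset: float = 1.0) -> np.ndarray:
    """ln(duration + offset) (durations in ms, offset keeps 0 finite)."""
    d = np.asarray(durations, dtype=float)
    if np.any(d < 0):
        raise ValueError("durations must be non-negative")
    return np.log(d + offset)


def standardize(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scores plus the (mean, std) used; zero-variance columns error."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column; drop it before fitting")
    return (X - mu) / sd, mu, sd


def ridge_fit(X, y, lam: float, feature_names=None,
              assume_standardized: bool = True) -> RegressionResult:
    """Closed-form ridge solution with unpenalized intercept.

    X is expected column-standardized (z-scored); pass
    ``assume_standardized=False`` to have it standardized here.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) and y (n,)")
    n, p = X.shape
    if n <= 2:
        raise ValueError("need more than two samples")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not assume_standardized:
        X, _, _ = standardize(X)
    # centering makes the intercept separable: beta0 = mean(y)
    yc = y - y.mean()
    A = X.T @ X / n + lam * np.eye(p)
    b = X.T @ yc / n
    if lam == 0:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "singular normal equations at lambda = 0 (collinear features); "
                "use lambda > 0")
    beta = np.linalg.solve(A, b)
    names = tuple(feature_names) if feature_names is not None \
        else tuple(f"x{i}" for i in range(p))
    return RegressionResult(beta, float(y.mean()), float(lam), None, names)


def _fold_indices(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return np.array_split(perm, k)


def cv_lambda(X, y, lambdas=DEFAULT_LAMBDA_GRID, k: int = 5,
              seed: int = 0, feature_names=None,
              rule: str = "1se") -> RegressionResult:
    """Pick lambda on a grid by k-fold CV (mean held-out squared error).

    Folds are a seeded permutation.  ``rule='min'`` takes the score minimum
    (larger lambda on exact ties); the default ``rule='1se'`` takes the
    largest lambda within one standard error of the minimum, preferring
    shrinkage whenever the data cannot distinguish the fits.  Returns the
    refit on all data at the winner.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    rng = np.random.default_rng(seed)
    folds = _fold_indices(len(y), k, rng)
    fold_scores = np.zeros((k, lambdas.size))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        Xtr, mu, sd = standardize(X[train_idx])
        Xte = (X[test_idx] - mu) / sd
        for li, lam in enumerate(lambdas):
            res = ridge_fit(Xtr, y[train_idx], lam)
            pred = res.beta0 + Xte @ res.beta
            fold_scores[f, li] = np.mean((y[test_idx] - pred) ** 2)
    scores = fold_scores.mean(axis=0)
    order = np.argsort(lambdas)
    i_min = order[np.argmin(scores[order])]
    if rule == "min":
        best = np.flatnonzero(scores <= scores[i_min] + 1e-12).max()
    else:
        se = fold_scores[:, i_min].std(ddof=1) / np.sqrt(k)
        ok = order[scores[order] <= scores[i_min] + se]
        best = ok[np.argmax(lambdas[ok])]
    Xs, _, _ = standardize(X)
    out = ridge_fit(Xs, y, float(lambdas[best]), feature_names)
    out.cv_score = float(scores[best])
    return out


def importance_ranking(result: RegressionResult) -> list[tuple[str, float]]:
    """Features ordered by |beta| (descending, stable: ties keep input order)."""
    order = np.argsort(-np.abs(result.beta), kind="stable")
    return [(result.feature_names[i], float(result.beta[i])) for i in order]


def impute_undefined(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Replace NaN feature entries by the column median; report counts."""
    counts = table.isna().sum()
    return table.fillna(table.median(numeric_only=True)), counts


# ---------------------------------------------------------------------------
# Hartigan dip test of unimodality
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dip_sorted(x):
    """Dip statistic of sorted data.

    D = min over mode positions m of the sup-norm distance between the
    empirical cdf and the best cdf that is convex left of m and concave
    right of m.  For each candidate mode the best convex (concave) sup-norm
    approximant on the left (right) is the greatest convex minorant (least
    concave majorant) shifted by half its maximal gap.
    """
    n = x.shape[0]
    if n < 4 or x[0] == x[n - 1]:
        return 0.0
    # empirical cdf value right after x[i]
    F = (np.arange(n) + 1.0) / n
    # left_gap[m]: max gap between F and the GCM of points (x[0..m], F[0..m])
    left_gap = np.zeros(n)
    hull = np.empty(n, dtype=np.int64)
    for m in range(n):
        # build GCM hull of prefix [0..m] (monotone chain, lower hull)
        k = 0
        for i in range(m + 1):
            while k >= 2:
                a, b = hull[k - 2], hull[k - 1]
                # drop b if it lies above segment a-i
                if (F[b] - F[a]) * (x[i] - x[a]) >= (F[i] - F[a]) * (x[b] - x[a]):
                    k -= 1
                else:
                    break
            hull[k] = i
            k += 1
        # max vertical gap F - gcm over the prefix
        g = 0.0
        seg = 0
        for i in range(m + 1):
            while seg < k - 1 and x[hull[seg + 1]] < x[i]:
                seg += 1
            a = hull[seg]
            b = hull[min(seg + 1, k - 1)]
            if x[b] > x[a]:
                y = F[a] + (F[b] - F[a]) * (x[i] - x[a]) / (x[b] - x[a])
            else:
                y = F[a]
            # compare against the cdf just below the jump as well
            lo = F[i] - 1.0 / n
            if F[i] - y > g:
                g = F[i] - y
            if y - lo > g:
                g = y - lo
        left_gap[m] = g
    # right_gap[m]: same with the LCM of the suffix [m..n-1]
    right_gap = np.zeros(n)
    for m in range(n - 1, -1, -1):
        k = 0
        for i in range(n - 1, m - 1, -1):
            while k >= 2:
                a, b = hull[k - 2], hull[k - 1]
                if (F[b] - F[a]) * (x[i] - x[a]) <= (F[i] - F[a]) * (x[b] - x[a]):
                    k -= 1
                else:
                    break
            hull[k] = i
            k += 1
        g = 0.0
        seg = 0
        for i in range(n - 1, m - 1, -1):
            while seg < k - 1 and x[hull[seg + 1]] > x[i]:
                seg += 1
            a = hull[seg]
            b = hull[min(seg + 1, k - 1)]
            if x[a] > x[b]:
                y = F[b] + (F[a] - F[b]) * (x[i] - x[b]) / (x[a] - x[b])
            else:
                y = F[a]
            lo = F[i] - 1.0 / n
            if y - lo > g:
                g = y - lo
            if F[i] - y > g:
                g = F[i] - y
        right_gap[m] = g
    d = 1e9
    for m in range(n):
        dm = max(left_gap[m], right_gap[m])
        if dm < d:
            d = dm
    return 0.5 * d


def dip_statistic(x) -> float:
    """Hartigan dip statistic: sup-norm distance to the nearest unimodal cdf."""
    x = np.sort(np.asarray(x, dtype=float))
    return float(_dip_sorted(x))


def dip_test(x, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Dip test of unimodality; p-value by uniform-null bootstrap.

    Returns (dip, p).  Small p rejects unimodality (the sample is at least
    bimodal).  The null distribution is the dip of ``n_boot`` uniform samples
    of the same size, the calibration Hartigan's test prescribes.
    """
    x = np.asarray(x, dtype=float)
    d = dip_statistic(x)
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for b in range(n_boot):
        null[b] = _dip_sorted(np.sort(rng.random(x.size)))
    p = float((1.0 + np.sum(null >= d)) / (n_boot + 1.0))
    return d, p
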