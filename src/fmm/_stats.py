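"""Shared statistical primitives: rank-sum tests, multiple-testing
corrections, and a ridge-stabilized logistic likelihood-ratio test.

The rank-sum test switches between an exact tie-aware enumeration (small
samples) and the tie-corrected normal approximation with continuity
correction (everything else), matching the behaviour expected of the
standard two-sample Wilcoxon used for marker detection.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

EXACT_RANKSUM_MAX_N = 30


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value, ties handled via midranks.

    Enumerates the exact null distribution of the group-1 rank sum over all
    C(n1+n2, n1) assignments by dynamic programming on doubled midranks
    (doubling makes midranks integral).  Two-sided p = min(1, 2*min(lower,
    upper tail)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks2 = np.round(2 * _midranks(np.concatenate([x, y]))).astype(int)
    w_obs = int(ranks2[:n1].sum())
    max_sum = int(ranks2.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        # iterate k downwards so each item is used at most once
        for k in range(min(n1, n1) - 1, -1, -1):
            row = dp[k]
            if row.any():
                dp[k + 1, r:] += row[: max_sum + 1 - r]
    dist = dp[n1]
    total = dist.sum()
    lower = dist[: w_obs + 1].sum() / total
    upper = dist[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def ranksum_matrix(values: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values for every row of ``values`` (features x cells),
    comparing cells where ``in_mask`` is True against the rest.

    Uses the exact enumeration when the total cell count is small enough,
    otherwise the tie-corrected normal approximation with continuity
    correction, vectorized across rows.
    """
    values = np.asarray(values, dtype=float)
    in_mask = np.asarray(in_mask, dtype=bool)
    n = values.shape[1]
    n1 = int(in_mask.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n <= EXACT_RANKSUM_MAX_N:
        return np.array(
            [exact_ranksum_p(row[in_mask], row[~in_mask]) for row in values]
        )
    ranks = sps.rankdata(values, method="average", axis=1)
    w = ranks[:, in_mask].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    # tie correction per row
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (w - mu - np.sign(w - mu) * 0.5) / sigma
    return np.minimum(1.0, 2.0 * sps.norm.sf(np.abs(z)))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bonferroni_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if m is None:
        m = len(p)
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# ridge-stabilized logistic regression


def logistic_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -30, 30)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-8,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[np.ndarray, float]:
    """Newton-fit a logistic regression with a tiny ridge penalty.

    The ridge keeps the Hessian invertible under perfect separation; the
    returned log-likelihood is the unpenalized one.  The intercept column is
    expected to be included in X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ll = logistic_loglik(X, y, beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped step: halve until the unpenalized log-likelihood is not worse
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = logistic_loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if abs(ll_new - ll) < tol:
            ll = ll_new
            break
        ll = ll_new
    return beta, ll


def logistic_lr_test(
    x: np.ndarray, y: np.ndarray, latent: np.ndarray | None = None
) -> tuple[float, float]:
    """Likelihood-ratio test for a single predictor ``x`` of binary ``y``,
    optionally adjusting for ``latent`` covariates present in both models.

    Returns (LR statistic, chi-square p with df=1).
    """
    n = len(y)
    cols_null = [np.ones(n)]
    if latent is not None:
        latent = np.atleast_2d(np.asarray(latent, dtype=float))
        if latent.shape[0] == n:
            latent = latent.T
        for row in latent:
            # constant covariates carry no information and break the Hessian scale
            if np.ptp(row) > 0:
                cols_null.append((row - row.mean()) / (row.std() + 1e-12))
    X_null = np.column_stack(cols_null)
    xs = np.asarray(x, dtype=float)
    if np.ptp(xs) > 0:
        xs = (xs - xs.mean()) / xs.std()
    X_full = np.column_stack([X_null, xs])
    _, ll_null = fit_logistic(X_null, y)
    _, ll_full = fit_logistic(X_full, y)
    stat = max(0.0, 2.0 * (ll_full - ll_null))
    p = float(sps.chi2.sf(stat, df=1))
    return stat, p
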