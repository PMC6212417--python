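"""Shared statistical kernels.

Every enrichment-style operation in the package routes through the single
hypergeometric kernel here; the rank tests and the two-sample KS statistic
are built in-package (the test-suite cross-checks them against independent
oracles), with scipy distributions supplying tail probabilities only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

# ---------------------------------------------------------------------------
# Pearson correlation


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-distributed p-value.

    Returns (nan, nan) for constant input, which callers must treat as
    non-significant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("pearson requires length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0))


def pearson_rows(matrix, vector) -> np.ndarray:
    """Pearson r of each matrix row against `vector` (constant rows -> nan)."""
    m = np.asarray(matrix, float)
    v = np.asarray(vector, float)
    mc = m - m.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    vnorm = np.sqrt(vc @ vc)
    rnorm = np.sqrt((mc * mc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ vc) / (rnorm * vnorm)
    return np.clip(r, -1.0, 1.0)


def pearson_p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    r = np.asarray(r, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * sps.t.sf(t, n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# Fisher's exact / hypergeometric kernel


def fet_overrep(overlap: int, set_a: int, set_b: int, universe: int) -> float:
    """One-sided (over-representation) hypergeometric p for a 2x2 overlap.

    P(X >= overlap) with X ~ Hypergeom(universe, set_a, set_b).
    """
    if min(overlap, set_a, set_b) < 0 or universe < max(set_a, set_b):
        raise ValueError("inconsistent 2x2 margins")
    if overlap == 0:
        return 1.0
    return float(sps.hypergeom.sf(overlap - 1, universe, set_a, set_b))


def fet_two_sided(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table."""
    table = np.asarray(table, int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("FET requires a non-negative 2x2 table")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Wilcoxon–Mann–Whitney

_ENUM_LIMIT = 500_000  # max C(n, n1) for full enumeration


def _rank_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for group x using midranks (tie-aware)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def _wmw_enumerate(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all group assignments (tie-safe)."""
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in combinations(range(n), n1)]
    )
    total = us.size
    p_le = np.count_nonzero(us <= u_obs + 1e-9) / total
    p_ge = np.count_nonzero(us >= u_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _wmw_exact_no_ties(n1: int, n2: int, u_obs: float) -> float:
    """Exact two-sided p via the rank-sum counting DP (no ties)."""
    n = n1 + n2
    max_u = n1 * n2
    # counts[j, u] = number of j-subsets of ranks seen so far with U = u
    counts = np.zeros((n1 + 1, max_u + 1), dtype=float)
    counts[0, 0] = 1.0
    for i in range(1, n + 1):
        upper = min(n1, i)
        for j in range(upper, 0, -1):
            # adding rank i as the j-th member contributes i - j to U
            shift = i - j
            if shift > max_u:
                continue
            counts[j, shift:] += counts[j - 1, : max_u + 1 - shift]
    dist = counts[n1]
    total = dist.sum()
    u = int(round(u_obs))
    p_le = dist[: u + 1].sum() / total
    p_ge = dist[u:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wmw_test(x, y, *, exact_max_group: int = 8) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney test; returns (U, p).

    Exact when the smaller group has <= `exact_max_group` observations
    (full enumeration when affordable — always for total n <= 12 — else the
    no-tie counting distribution); otherwise the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if min(n1, n2) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return n1 * n2 / 2.0, 1.0
    u = _rank_u(x, y)
    has_ties = np.unique(pooled).size < pooled.size
    if min(n1, n2) <= exact_max_group:
        if comb(n1 + n2, n1) <= _ENUM_LIMIT:
            return u, _wmw_enumerate(x, y)
        if not has_ties:
            return u, _wmw_exact_no_ties(n1, n2, u)
    # normal approximation, tie-corrected variance
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    mu = n1 * n2 / 2.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)  # continuity correction
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return u, float(min(p, 1.0))


def wmw_rows(matrix, group_mask) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation WMW p per matrix row.

    `group_mask` marks group 1 columns. Constant rows get p = 1.
    """
    m = np.asarray(matrix, float)
    mask = np.asarray(group_mask, bool)
    n1 = int(mask.sum())
    n2 = int((~mask).sum())
    if min(n1, n2) < 1:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    r1 = ranks[:, mask].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    tie_term = np.empty(m.shape[0])
    for i in range(m.shape[0]):
        _, counts = np.unique(m[i], return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(u - mu) - 0.5) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(np.maximum(z, 0.0))
    p = np.where(sigma2 <= 0, 1.0, np.minimum(p, 1.0))
    return p


# ---------------------------------------------------------------------------
# Two-sample Kolmogorov–Smirnov

_KS_ENUM_LIMIT = 200_000


@dataclass(frozen=True)
class KsResult:
    statistic: float
    pvalue: float


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    x = np.sort(x)
    y = np.sort(y)
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def ks_two_sample(x, y) -> KsResult:
    """Two-sided two-sample KS test.

    Statistic is the max pooled-CDF gap. For small samples the p-value is
    exact (enumeration of assignments, valid under ties); otherwise the
    Smirnov asymptotic distribution with effective size n1*n2/(n1+n2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if min(n1, n2) < 1:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(x, y)
    if comb(n1 + n2, n1) <= _KS_ENUM_LIMIT:
        pooled = np.concatenate([x, y])
        n = pooled.size
        count = 0
        total = 0
        idx_all = frozenset(range(n))
        for idx in combinations(range(n), n1):
            a = pooled[list(idx)]
            b = pooled[list(idx_all - set(idx))]
            total += 1
            if _ks_statistic(a, b) >= d - 1e-12:
                count += 1
        return KsResult(d, count / total)
    en = n1 * n2 / (n1 + n2)
    p = float(sps.kstwo.sf(d, int(round(en))))
    return KsResult(d, float(np.clip(p, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# FDR machinery


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-tolerant: NaN stays NaN)."""
    p = np.asarray(pvalues, float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    adj = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def permutation_fdr(observed, null, n_perm: int) -> np.ndarray:
    """Empirical FDR from a pooled permutation null.

    ``FDR(t) = [mean per-permutation count of null >= t] / #{observed >= t}``
    monotonized so that a larger statistic never has a larger FDR. Larger
    statistic = more significant. `null` pools all permutations (and, when
    used across features, all features). Ties in `observed` share one FDR.
    """
    obs = np.asarray(observed, float)
    null = np.asarray(null, float).ravel()
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100: permutation FDR tail is unstable", stacklevel=2)
    null_sorted = np.sort(null)
    obs_sorted = np.sort(obs)
    fdr = np.empty_like(obs)
    # for each observed t: mean null count >= t, over observed count >= t
    n_null_ge = null_sorted.size - np.searchsorted(null_sorted, obs, side="left")
    n_obs_ge = obs_sorted.size - np.searchsorted(obs_sorted, obs, side="left")
    fdr = (n_null_ge / n_perm) / np.maximum(n_obs_ge, 1)
    fdr = np.minimum(fdr, 1.0)
    # q-value of t = min raw FDR over thresholds <= t (those still call t
    # significant); ascending running min => non-increasing in the statistic
    order = np.argsort(obs, kind="mergesort")
    out = np.empty_like(fdr)
    out[order] = np.minimum.accumulate(fdr[order])
    return out


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-sample t test; returns (t, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.array_equal(np.sort(x), np.sort(y)):
        return 0.0, 1.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
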