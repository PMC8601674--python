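"""Ordered-trend, paired, multi-group, correlation and mediation statistics.

This is the study's statistical layer for a cohort spanning an ordered
severity gradient: the Jonckheere-Terpstra ordered-medians test (exact,
permutation, and tie-corrected normal methods), Wilcoxon signed-rank for
rest/stress pairs, Kruskal-Wallis with Dunn post hoc z tests, Pearson
correlation / simple linear regression, and Preacher-Hayes single-mediator
regression with bias-corrected case-resampling bootstrap of the indirect
effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import GROUP_ORDER, CohortTable

__all__ = [
    "JTResult",
    "WilcoxonResult",
    "KruskalDunnResult",
    "LinRegResult",
    "MediationResult",
    "jt_statistic",
    "jonckheere_terpstra",
    "wilcoxon_signed_rank",
    "kruskal_wallis_dunn",
    "pearson_linreg",
    "mediation_bootstrap",
]


# ---------------------------------------------------------------- results


@dataclass(frozen=True)
class JTResult:
    statistic: float
    p_one_sided: float
    p_two_sided: float
    method: str
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    n_zero_dropped: int
    method: str
    alternative: str


@dataclass(frozen=True)
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    adjust: str


@dataclass(frozen=True)
class LinRegResult:
    r: float
    slope: float
    intercept: float
    p_value: float
    n: int


@dataclass(frozen=True)
class MediationResult:
    path_a: float
    path_b: float
    direct_effect: float
    indirect_effect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_used: int
    significant: bool


# ---------------------------------------------------------------- helpers


def _resolve_groups(data, metric: str | None) -> list[np.ndarray]:
    if isinstance(data, CohortTable):
        if metric is None:
            raise ValueError("metric is required with a CohortTable")
        groups = data.groups(metric)
    else:
        groups = [np.asarray(g, dtype=float) for g in data]
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    return groups


def jt_statistic(groups: list[np.ndarray]) -> float:
    """J = sum over ordered group pairs of Mann-Whitney counts (ties as 1/2)."""
    j = 0.0
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            a = groups[gi][:, None]
            b = groups[gj][None, :]
            j += np.sum(a < b) + 0.5 * np.sum(a == b)
    return float(j)


def _mw_counts(m: int, n: int, _memo={}) -> np.ndarray:
    """Counts of the Mann-Whitney U null distribution (no ties), u = 0..m*n.

    Recurrence N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1).
    """
    if m == 0 or n == 0:
        return np.ones(1)
    key = (m, n) if m >= n else (n, m)
    if key in _memo:
        return _memo[key]
    a = _mw_counts(m - 1, n)
    b = _mw_counts(m, n - 1)
    out = np.zeros(m * n + 1)
    out[n : n + len(a)] += a
    out[: len(b)] += b
    _memo[key] = out
    return out


def _jt_exact_null_pmf(sizes: list[int]) -> np.ndarray:
    """Exact JT null pmf as the convolution of independent MW nulls.

    With no ties, J decomposes as a sum of independent Mann-Whitney
    statistics U(N_{h-1}, n_h), h = 2..G; their null pmfs convolve to the
    JT null. This is an O(n^2 max(J)) dynamic program, not an enumeration.
    """
    pmf = np.ones(1)
    acc = sizes[0]
    for nh in sizes[1:]:
        counts = _mw_counts(acc, nh)
        pmf = np.convolve(pmf, counts / counts.sum())
        acc += nh
    return pmf


def jonckheere_terpstra(
    data,
    metric: str | None = None,
    method: str = "normal_approx",
    n_perm: int = 10_000,
    seed: int = 0,
) -> JTResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    The one-sided p is against the increasing alternative (later groups
    stochastically larger); the two-sided p doubles the smaller tail.
    Methods: 'exact' (tie-free dynamic-programming null), 'permutation'
    (label permutations, seeded), 'normal_approx' (tie-corrected variance,
    no continuity correction).
    """
    groups = _resolve_groups(data, metric)
    if len(groups) < 2:
        raise ValueError("need at least 2 ordered groups")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    j_obs = jt_statistic(groups)

    if method == "exact":
        if len(np.unique(pooled)) != n:
            raise ValueError("exact method requires tie-free data; use permutation")
        pmf = _jt_exact_null_pmf(sizes)
        support = np.arange(len(pmf))
        p_ge = float(pmf[support >= j_obs - 1e-9].sum())
        p_le = float(pmf[support <= j_obs + 1e-9].sum())
        p_one = p_ge
        p_two = min(1.0, 2.0 * min(p_ge, p_le))
    elif method == "permutation":
        if n_perm < 1000:
            raise ValueError("use at least 1000 permutations")
        rng = np.random.default_rng(seed)
        c = (pooled[:, None] < pooled[None, :]) + 0.5 * (
            pooled[:, None] == pooled[None, :]
        )
        labels = np.repeat(np.arange(len(sizes)), sizes)
        mask = (labels[:, None] < labels[None, :]).astype(float)
        ge = le = 0
        chunk = max(1, min(n_perm, int(4e7 // (n * n))))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            perms = np.argsort(rng.random((b, n)), axis=1)
            cg = c[perms[:, :, None], perms[:, None, :]]
            jp = np.tensordot(cg, mask, axes=([1, 2], [0, 1]))
            ge += int(np.sum(jp >= j_obs - 1e-9))
            le += int(np.sum(jp <= j_obs + 1e-9))
            done += b
        p_one = (ge + 1) / (n_perm + 1)
        p_le = (le + 1) / (n_perm + 1)
        p_two = min(1.0, 2.0 * min(p_one, p_le))
    elif method == "normal_approx":
        sz = np.asarray(sizes, dtype=float)
        mean = (n**2 - np.sum(sz**2)) / 4.0
        _, t = np.unique(pooled, return_counts=True)
        t = t.astype(float)
        a = (
            n * (n - 1) * (2 * n + 5)
            - np.sum(sz * (sz - 1) * (2 * sz + 5))
            - np.sum(t * (t - 1) * (2 * t + 5))
        )
        b = np.sum(sz * (sz - 1) * (sz - 2)) * np.sum(t * (t - 1) * (t - 2))
        cc = np.sum(sz * (sz - 1)) * np.sum(t * (t - 1))
        var = a / 72.0
        if n > 2:
            var += b / (36.0 * n * (n - 1) * (n - 2))
        var += cc / (8.0 * n * (n - 1))
        if var <= 0:
            raise ValueError("degenerate data: zero JT variance")
        z = (j_obs - mean) / np.sqrt(var)
        p_one = float(sps.norm.sf(z))
        p_two = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")

    return JTResult(
        statistic=j_obs,
        p_one_sided=float(p_one),
        p_two_sided=float(min(p_two, 1.0)),
        method=method,
        group_sizes=tuple(sizes),
    )


def wilcoxon_signed_rank(
    rest,
    stress=None,
    alternative: str = "two-sided",
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired values (or precomputed differences).

    Zero differences are dropped before ranking. The null is exact for
    n <= 20 tie-free differences, and a normal approximation with
    continuity correction beyond. The statistic is the sum of ranks of the
    positive differences.
    """
    rest = np.asarray(rest, dtype=float)
    d = np.asarray(stress, dtype=float) - rest if stress is not None else rest
    nz = d[d != 0]
    n_dropped = len(d) - len(nz)
    if len(nz) == 0:
        raise ValueError("all differences are zero")
    if len(nz) < 5:
        raise ValueError("need at least 5 non-zero differences for a p-value")
    tie_free = len(np.unique(np.abs(nz))) == len(nz)
    method = "exact" if (len(nz) <= 20 and tie_free) else "approx"
    res = sps.wilcoxon(
        nz, alternative=alternative, method=method, correction=(method == "approx")
    )
    w_plus = float(np.sum(sps.rankdata(np.abs(nz))[nz > 0]))
    return WilcoxonResult(
        statistic=w_plus,
        p_value=float(res.pvalue),
        n_used=len(nz),
        n_zero_dropped=n_dropped,
        method=method,
        alternative=alternative,
    )


def kruskal_wallis_dunn(
    data,
    metric: str | None = None,
    adjust: str = "holm",
    group_names: list[str] | None = None,
) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus with Dunn post hoc pairwise comparisons.

    The omnibus H is tie-corrected. Dunn z statistics use pooled mean ranks
    with the tie-corrected variance; pairwise p values are adjusted with
    Holm's method by default (configurable via any statsmodels method name).
    """
    groups = _resolve_groups(data, metric)
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    names = group_names or (
        list(GROUP_ORDER)[: len(groups)]
        if isinstance(data, CohortTable)
        else [f"g{i}" for i in range(len(groups))]
    )
    h, p = sps.kruskal(*groups)

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start : start + s].mean())
        start += s
    _, t = np.unique(pooled, return_counts=True)
    tie_term = np.sum(t**3 - t) / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(groups)):
        for k in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[k]))
            z = (mean_ranks[i] - mean_ranks[k]) / se
            rows.append(
                {"group1": names[i], "group2": names[k], "z": z,
                 "p_raw": 2.0 * sps.norm.sf(abs(z))}
            )
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method=adjust)[1]
    return KruskalDunnResult(
        h_statistic=float(h), p_value=float(p), pairwise=pairwise, adjust=adjust
    )


def pearson_linreg(x, y) -> LinRegResult:
    """Pearson correlation and simple linear regression (t-test p, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    fit = sps.linregress(x, y)
    return LinRegResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def _batched_ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients for a batch of (n, p) designs; (B, n, p) -> (B, p)."""
    gram = np.einsum("bni,bnj->bij", design, design)
    rhs = np.einsum("bni,bn->bi", design, y)
    try:
        return np.linalg.solve(gram, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.einsum("bij,bj->bi", np.linalg.pinv(gram), rhs)


def mediation_bootstrap(
    data,
    x_metric: str,
    mediator_metric: str,
    y_metric: str,
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Single-mediator regression with bootstrapped indirect effect.

    Path a regresses the mediator on the exposure; path b and the direct
    effect come from regressing the outcome on exposure and mediator
    jointly. The indirect effect a*b gets a bias-corrected (BC) percentile
    interval from case-resampling bootstrap with a fixed seed; significance
    means the CI excludes zero. Complete-case analysis on raw variables.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    df = data.df if isinstance(data, CohortTable) else pd.DataFrame(data)
    sub = df[[x_metric, mediator_metric, y_metric]].dropna()
    n = len(sub)
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, have {n}")
    x = sub[x_metric].to_numpy(float)
    m = sub[mediator_metric].to_numpy(float)
    y = sub[y_metric].to_numpy(float)
    ones = np.ones(n)
    design_m = np.column_stack([ones, x])
    design_y = np.column_stack([ones, x, m])
    if np.linalg.matrix_rank(design_y) < 3:
        raise ValueError("singular design: exposure and mediator are collinear")

    a_hat = np.linalg.lstsq(design_m, m, rcond=None)[0][1]
    coef_y = np.linalg.lstsq(design_y, y, rcond=None)[0]
    direct, b_hat = coef_y[1], coef_y[2]
    indirect_hat = a_hat * b_hat

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    ones_b = np.ones_like(xb)
    a_b = _batched_ols(np.stack([ones_b, xb], axis=2), mb)[:, 1]
    coefs = _batched_ols(np.stack([ones_b, xb, mb], axis=2), yb)
    indirect_b = a_b * coefs[:, 2]

    # bias-corrected percentile interval
    prop = np.clip(
        np.mean(indirect_b < indirect_hat), 1.0 / (n_boot + 1), n_boot / (n_boot + 1)
    )
    z0 = sps.norm.ppf(prop)
    alpha = (1.0 - ci_level) / 2.0
    lo_q = sps.norm.cdf(2 * z0 + sps.norm.ppf(alpha))
    hi_q = sps.norm.cdf(2 * z0 + sps.norm.ppf(1.0 - alpha))
    ci_low, ci_high = np.quantile(indirect_b, [lo_q, hi_q])

    return MediationResult(
        path_a=float(a_hat),
        path_b=float(b_hat),
        direct_effect=float(direct),
        indirect_effect=float(indirect_hat),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
        n_used=n,
        significant=bool(ci_low > 0 or ci_high < 0),
    )
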