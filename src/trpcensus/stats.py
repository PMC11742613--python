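"""Group-comparison statistics implemented from first principles.

Three tests cover everything the census and depth pipelines report:

* Mann-Whitney U (midranks; exact enumeration for small pooled samples, normal
  approximation with tie and continuity correction otherwise),
* one-way ANOVA (F = MSB/MSW against the F distribution),
* Tukey's HSD (studentized-range p-values by numerical quadrature, with the
  pairwise harmonic-mean sample size for unequal group sizes).

The implementations are deliberately self-contained — scipy supplies only the
normal, F and chi distributions and rank utilities — so that the tests can
cross-check them against independent references.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, special, stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "anova_oneway",
    "tukey_hsd",
    "studentized_range_cdf",
]

_ALTERNATIVES = ("two-sided", "greater", "less")

#: pooled-sample size at or below which the Mann-Whitney p is computed exactly
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (or one pairwise comparison)."""

    method: str
    statistic: float
    p_value: float
    alternative: str = "two-sided"
    tie_corrected: bool = False
    group_sizes: tuple[int, ...] = ()
    pair: tuple[int, int] | None = None
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if not math.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_from_ranks(rank_sum_x: float, n1: int) -> float:
    return rank_sum_x - n1 * (n1 + 1) / 2.0


def _exact_mwu_pvalues(pooled: np.ndarray, n1: int, u_obs: float) -> tuple[float, float]:
    """P(U <= u_obs) and P(U >= u_obs) by enumeration of all C(N, n1) splits."""
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    total = math.comb(n, n1)
    le = ge = 0
    for combo in itertools.combinations(range(n), n1):
        u = _u_from_ranks(ranks[list(combo)].sum(), n1)
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    return le / total, ge / total


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact: bool | None = None,
) -> TestResult:
    """Mann-Whitney U rank test for two independent samples.

    The statistic is U for ``x`` computed from midranks.  For pooled sample
    sizes up to 12 the p-value comes from exact enumeration of all
    ``C(n1+n2, n1)`` rank assignments; above that, from the normal
    approximation with tie correction and a 0.5 continuity correction.
    ``exact`` overrides the automatic choice.

    ``alternative="less"`` tests whether ``x`` tends to be smaller than ``y``.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = _u_from_ranks(ranks[:n1].sum(), n1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if exact is None:
        exact = n1 + n2 <= EXACT_ENUMERATION_LIMIT
    if exact:
        p_le, p_ge = _exact_mwu_pvalues(pooled, n1, u)
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "Mann-Whitney U (exact)"
    else:
        mean = n1 * n2 / 2.0
        n = n1 + n2
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            # every observation identical: U is degenerate at its mean
            p = 1.0
        else:
            sd = math.sqrt(var)
            p_greater = sps.norm.sf((u - 0.5 - mean) / sd)
            p_less = sps.norm.cdf((u + 0.5 - mean) / sd)
            if alternative == "less":
                p = p_less
            elif alternative == "greater":
                p = p_greater
            else:
                p = min(1.0, 2.0 * min(p_less, p_greater))
        method = "Mann-Whitney U (normal approx.)"

    return TestResult(
        method=method,
        statistic=float(u),
        p_value=float(p),
        alternative=alternative,
        tie_corrected=has_ties,
        group_sizes=(n1, n2),
    )


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------


def _anova_sums(groups: Sequence[np.ndarray]) -> tuple[float, float, int, int]:
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return float(ssb), float(ssw), k, n_total


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MSB/MSW on (k-1, N-k) df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs at least two observations")
    ssb, ssw, k, n_total = _anova_sums(arrays)
    df_between, df_within = k - 1, n_total - k
    msb = ssb / df_between
    msw = ssw / df_within
    if msw == 0:
        if msb == 0:
            return TestResult(
                "one-way ANOVA", 0.0, 1.0, group_sizes=tuple(g.size for g in arrays),
                extra={"df_between": df_between, "df_within": df_within},
            )
        raise ValueError("zero within-group variance with unequal means")
    f = msb / msw
    p = float(sps.f.sf(f, df_between, df_within))
    return TestResult(
        "one-way ANOVA",
        float(f),
        p,
        group_sizes=tuple(g.size for g in arrays),
        extra={"df_between": df_between, "df_within": df_within, "msw": msw},
    )


# ---------------------------------------------------------------------------
# Tukey HSD and the studentized-range distribution
# ---------------------------------------------------------------------------


def _prange_cdf_scaled(x: float, k: int, n_nodes: int = 160) -> float:
    """P(range of k standard normals <= x), Gauss-Legendre quadrature."""
    if x <= 0:
        return 0.0
    lo, hi = -9.0, 9.0 + x
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    z = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * weights
    phi = np.exp(-0.5 * z**2) / math.sqrt(2 * math.pi)
    inner = (special.ndtr(z) - special.ndtr(z - x)) ** (k - 1)
    val = k * float(np.sum(w * phi * inner))
    return min(1.0, max(0.0, val))


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range with ``k`` groups and ``df`` error df.

    Integrates the range CDF of ``k`` standard normals against the density of
    ``s = chi_df / sqrt(df)`` by adaptive quadrature (absolute tolerance 1e-6).
    ``df=inf`` reduces to the plain normal-range CDF.
    """
    if q <= 0:
        return 0.0
    if k < 2:
        raise ValueError("k must be >= 2")
    if not math.isfinite(df):
        return _prange_cdf_scaled(q, k)

    log_norm = (1 - df / 2.0) * math.log(2.0) + (df / 2.0) * math.log(df) - special.gammaln(
        df / 2.0
    )

    def outer(s: float) -> float:
        if s <= 0:
            return 0.0
        log_dens = log_norm + (df - 1) * math.log(s) - df * s * s / 2.0
        return math.exp(log_dens) * _prange_cdf_scaled(q * s, k)

    val, _err = integrate.quad(outer, 0.0, np.inf, epsabs=1e-6, epsrel=1e-6, limit=200)
    return min(1.0, max(0.0, val))


def tukey_hsd(groups: Sequence[Sequence[float]]) -> list[TestResult]:
    """Tukey's honestly-significant-difference test on all group pairs.

    Each pair (i, j) gets q = |mean_i - mean_j| / sqrt(MSW / n_tilde) where
    ``n_tilde`` is the harmonic mean of the two group sizes (the Tukey-Kramer
    adjustment for unequal n), and a p-value from the studentized-range
    distribution with k groups and N - k error df.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs at least two observations")
    _ssb, ssw, k, n_total = _anova_sums(arrays)
    df_within = n_total - k
    msw = ssw / df_within
    if msw == 0:
        raise ValueError("zero within-group variance")
    results = []
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = arrays[i], arrays[j]
        n_tilde = 2.0 / (1.0 / gi.size + 1.0 / gj.size)
        diff = gi.mean() - gj.mean()
        q = abs(diff) / math.sqrt(msw / n_tilde)
        p = 1.0 - studentized_range_cdf(q, k, df_within)
        results.append(
            TestResult(
                "Tukey HSD",
                float(q),
                float(min(1.0, max(0.0, p))),
                group_sizes=(gi.size, gj.size),
                pair=(i, j),
                extra={"mean_diff": float(diff), "df_within": df_within, "k": k},
            )
        )
    return results
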