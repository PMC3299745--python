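"""Small-sample statistics for endpoint and diversity comparisons.

The experimental design is three replicates per treatment, so everything
here is tuned to very small n: a pooled-variance (Student) unpaired t-test
whose degrees of freedom are n1 + n2 - 2, one-way ANOVA with Tukey HSD for
the between-control comparison, Box-Cox transformation to stabilise the
endpoint distributions before those tests, and Spearman rank correlation —
with an exact permutation p-value where the full enumeration is feasible,
because the t-approximation is unreliable at n = 6.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "SampleGroup",
    "TestResult",
    "BoxCoxResult",
    "box_cox",
    "t_test_unpaired",
    "one_way_anova",
    "tukey_hsd",
    "spearman",
]

#: swap to the asymptotic p above this n; 8! = 40320 permutations is instant
EXACT_SPEARMAN_MAX_N = 8


@dataclass(frozen=True)
class SampleGroup:
    """A labelled set of replicate-level values entering a test."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValueError(f"group {self.label!r} is empty")
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", vals)

    @classmethod
    def of(cls, label, values) -> "SampleGroup":
        return cls(str(label), tuple(values))

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: "float | tuple[int, int]"
    p_value: float
    method: str
    labels: tuple[str, ...] = ()
    details: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BoxCoxResult:
    values: tuple[float, ...]
    lmbda: float
    shift: float


def box_cox(values, lmbda: "float | str" = "auto") -> BoxCoxResult:
    """Box-Cox power transform, with an automatic shift for zeros.

    y = ln x when lambda = 0, else (x**lambda - 1)/lambda. Zero-containing
    data are shifted by half the smallest positive value before transforming
    (the shift is recorded in the result); negative values are rejected.
    ``lmbda="auto"`` selects lambda by profile log-likelihood maximisation
    over [-5, 5].
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("box_cox requires at least one value")
    if np.any(x < 0):
        raise ValueError("box_cox requires non-negative values")
    shift = 0.0
    if np.any(x == 0):
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("box_cox requires at least one positive value")
        shift = float(positive.min()) / 2.0
        x = x + shift
    if lmbda == "auto":
        res = optimize.minimize_scalar(
            lambda lam: -sps.boxcox_llf(lam, x),
            bounds=(-5.0, 5.0),
            method="bounded",
        )
        lam = float(res.x)
    else:
        lam = float(lmbda)
    if lam == 0.0:
        y = np.log(x)
    else:
        y = (np.power(x, lam) - 1.0) / lam
    return BoxCoxResult(values=tuple(y.tolist()), lmbda=lam, shift=shift)


def t_test_unpaired(a: SampleGroup, b: SampleGroup) -> TestResult:
    """Pooled-variance (Student) two-sample t-test, two-sided.

    df = n1 + n2 - 2. Zero pooled variance is resolved explicitly: equal
    means give t = 0, p = 1; unequal means give an infinite-t marker with
    p = 0.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least 2 values")
    df = a.n + b.n - 2
    xa, xb = np.asarray(a.values), np.asarray(b.values)
    pooled_var = (
        (a.n - 1) * xa.var(ddof=1) + (b.n - 1) * xb.var(ddof=1)
    ) / df
    labels = (a.label, b.label)
    if pooled_var == 0.0:
        if xa.mean() == xb.mean():
            return TestResult(0.0, df, 1.0, "t-test (pooled)", labels)
        t = math.copysign(math.inf, xa.mean() - xb.mean())
        return TestResult(t, df, 0.0, "t-test (pooled)", labels)
    t, p = sps.ttest_ind(xa, xb, equal_var=True)
    return TestResult(float(t), df, float(p), "t-test (pooled)", labels)


def _group_arrays(groups: list[SampleGroup]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} needs at least 2 values")
    return [np.asarray(g.values) for g in groups]


def one_way_anova(groups: list[SampleGroup]) -> TestResult:
    """Standard one-way fixed-effects ANOVA; df = (k - 1, N - k)."""
    arrays = _group_arrays(groups)
    k = len(arrays)
    n_total = sum(len(x) for x in arrays)
    df = (k - 1, n_total - k)
    labels = tuple(g.label for g in groups)
    grand = np.concatenate(arrays)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in arrays)
    ss_between = sum(len(x) * (x.mean() - grand.mean()) ** 2 for x in arrays)
    if ss_between == 0.0:
        return TestResult(0.0, df, 1.0, "one-way ANOVA", labels)
    if ss_within == 0.0:
        return TestResult(math.inf, df, 0.0, "one-way ANOVA", labels)
    f, p = sps.f_oneway(*arrays)
    return TestResult(float(f), df, float(p), "one-way ANOVA", labels)


def tukey_hsd(groups: list[SampleGroup]) -> list[TestResult]:
    """All pairwise comparisons by Tukey's honestly-significant-difference test.

    p-values come from the studentized-range distribution at the ANOVA error
    df, N - k. Each result's statistic is the mean difference for that pair.
    Degenerate input (zero within-group variance everywhere) yields p = 1
    for equal-mean pairs and p = 0 otherwise.
    """
    arrays = _group_arrays(groups)
    k = len(arrays)
    error_df = sum(len(x) for x in arrays) - k
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in arrays)
    results: list[TestResult] = []
    if ss_within == 0.0:
        for i, j in itertools.combinations(range(k), 2):
            diff = float(arrays[i].mean() - arrays[j].mean())
            p = 1.0 if diff == 0.0 else 0.0
            stat = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            results.append(
                TestResult(stat, error_df, p, "Tukey HSD",
                           (groups[i].label, groups[j].label))
            )
        return results
    res = sps.tukey_hsd(*arrays)
    for i, j in itertools.combinations(range(k), 2):
        results.append(
            TestResult(
                float(res.statistic[i, j]),
                error_df,
                float(res.pvalue[i, j]),
                "Tukey HSD",
                (groups[i].label, groups[j].label),
            )
        )
    return results


def _rank_correlation(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    # Pearson correlation of average ranks — the definition of Spearman's r
    # under ties. Ranks always have nonzero variance here (checked upstream).
    cx = rank_x - rank_x.mean()
    cy = rank_y - rank_y.mean()
    return float((cx @ cy) / math.sqrt((cx @ cx) * (cy @ cy)))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with an exact permutation p at small n.

    r is the Pearson correlation of average ranks. For n <= 8 the two-sided
    p-value is computed by full enumeration of the n! rank permutations
    (counting |r_perm| >= |r_obs|); beyond that the usual t-approximation
    with n - 2 df is used. The asymptotic p is always available in
    ``details["p_asymptotic"]``. Zero rank variance (all-tied input) gives
    an undefined marker: statistic and p are NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires at least 3 pairs")
    rank_x = sps.rankdata(x)
    rank_y = sps.rankdata(y)
    if np.ptp(rank_x) == 0 or np.ptp(rank_y) == 0:
        return TestResult(
            math.nan, n - 2, math.nan, "Spearman rank (undefined: zero rank variance)"
        )
    r = _rank_correlation(rank_x, rank_y)
    if abs(r) < 1.0:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p_asym = 2.0 * sps.t.sf(abs(t), n - 2)
    else:
        p_asym = 0.0
    if n <= EXACT_SPEARMAN_MAX_N:
        threshold = abs(r) - 1e-12
        hits = 0
        total = 0
        for perm in itertools.permutations(rank_y):
            if abs(_rank_correlation(rank_x, np.asarray(perm))) >= threshold:
                hits += 1
            total += 1
        p = hits / total
        method = "Spearman rank (exact permutation)"
    else:
        p = p_asym
        method = "Spearman rank (t-approximation)"
    return TestResult(r, n - 2, p, method, details={"p_asymptotic": float(p_asym)})
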