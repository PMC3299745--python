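"""Box-Cox, pooled t-test, ANOVA/Tukey and Spearman at small n."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from clonediv.diversity import brillouin_diversity
from clonediv.stats import (
    SampleGroup,
    box_cox,
    one_way_anova,
    spearman,
    t_test_unpaired,
    tukey_hsd,
)

from conftest import TABLE1_COUNTS

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)
small_groups = st.lists(finite, min_size=2, max_size=6)


def group(label, values):
    return SampleGroup.of(label, values)


# ---------------------------------------------------------------- Box-Cox

def test_box_cox_identity_and_log_limits():
    assert box_cox([1, 2, 3], 1).values == pytest.approx((0, 1, 2))
    assert box_cox([1, math.e, math.e**2], 0).values == pytest.approx((0, 1, 2))


def test_box_cox_auto_recovers_lognormal_lambda():
    rng = np.random.default_rng(42)
    x = np.exp(rng.normal(0, 1, size=200))
    res = box_cox(x, "auto")
    assert -0.3 <= res.lmbda <= 0.3
    assert res.shift == 0.0


@pytest.mark.parametrize("true_lambda", [0.0, 0.5, 1.0])
def test_box_cox_auto_lambda_recovery(true_lambda):
    """Data built so the transform at true_lambda is Gaussian."""
    rng = np.random.default_rng(int(true_lambda * 10) + 1)
    # a generous spread keeps the profile likelihood informative in lambda
    z = rng.normal(6, 1.5, size=2000)
    x = np.exp(z) if true_lambda == 0 else (true_lambda * z + 1) ** (1 / true_lambda)
    assert abs(box_cox(x, "auto").lmbda - true_lambda) <= 0.25


def test_box_cox_shifts_zeros_by_half_smallest_positive():
    res = box_cox([0.0, 2.0, 4.0], 1)
    assert res.shift == pytest.approx(1.0)
    assert res.values[0] == pytest.approx(0.0)  # (0 + 1) - 1


def test_box_cox_rejects_negatives():
    with pytest.raises(ValueError):
        box_cox([-1.0, 2.0], 1)


# ---------------------------------------------------------------- t-test

def test_t_test_reproduces_diversity_contrast():
    """Control vs antibiotic Brillouin diversities give t_4 = 2.82, p = 0.048."""
    controls = [brillouin_diversity(TABLE1_COUNTS[k]) for k in ("SS", "Ac", "DMSO")]
    antibiotics = [brillouin_diversity(TABLE1_COUNTS[k]) for k in ("Cipr", "Sulf", "Trim")]
    res = t_test_unpaired(group("controls", controls), group("antibiotics", antibiotics))
    assert res.df == 4
    assert round(abs(res.statistic), 2) == 2.82
    assert res.p_value == pytest.approx(0.048, abs=0.002)


def test_t_test_hand_computed_value():
    res = t_test_unpaired(group("a", [1, 2, 3]), group("b", [4, 5, 6]))
    assert abs(res.statistic) == pytest.approx(3.6742346141747673)
    assert res.df == 4


def test_t_test_degenerate_variance():
    same = t_test_unpaired(group("a", [2, 2]), group("b", [2, 2]))
    assert same.statistic == 0.0 and same.p_value == 1.0
    apart = t_test_unpaired(group("a", [2, 2]), group("b", [3, 3]))
    assert math.isinf(apart.statistic) and apart.p_value == 0.0


@given(small_groups, small_groups)
def test_t_test_antisymmetric_and_affine_invariant(a_vals, b_vals):
    res = t_test_unpaired(group("a", a_vals), group("b", b_vals))
    swapped = t_test_unpaired(group("b", b_vals), group("a", a_vals))
    assert swapped.statistic == pytest.approx(-res.statistic, rel=1e-9, abs=1e-9)
    if math.isfinite(res.statistic):
        scaled = t_test_unpaired(
            group("a", [3.0 * v + 7.0 for v in a_vals]),
            group("b", [3.0 * v + 7.0 for v in b_vals]),
        )
        assert scaled.statistic == pytest.approx(res.statistic, rel=1e-6, abs=1e-6)


# ---------------------------------------------------------------- ANOVA / Tukey

def test_anova_identical_groups_give_zero_f():
    res = one_way_anova([group(str(i), [1, 2, 3]) for i in range(3)])
    assert res.statistic == 0.0 and res.df == (2, 6) and res.p_value == 1.0


def test_anova_hand_computed_value():
    res = one_way_anova([group("a", [1, 2, 3]), group("b", [2, 3, 4]), group("c", [6, 7, 8])])
    assert res.statistic == pytest.approx(21.0)
    assert res.df == (2, 6)


@given(small_groups, small_groups)
def test_anova_two_groups_is_squared_t(a_vals, b_vals):
    f = one_way_anova([group("a", a_vals), group("b", b_vals)])
    t = t_test_unpaired(group("a", a_vals), group("b", b_vals))
    if math.isfinite(t.statistic):
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-6, abs=1e-9)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-6, abs=1e-9)


def test_tukey_identical_groups():
    pairs = tukey_hsd([group(str(i), [5, 5, 5]) for i in range(3)])
    assert all(p.p_value == 1.0 for p in pairs)


def test_tukey_p_monotone_in_mean_gap():
    pairs = tukey_hsd(
        [group("a", [1, 2, 3]), group("b", [2, 3, 4]), group("c", [6, 7, 8])]
    )
    by_pair = {p.labels: p.p_value for p in pairs}
    assert by_pair[("a", "c")] < by_pair[("a", "b")]


def test_tukey_two_groups_equals_t_test():
    """With k = 2 the studentized range collapses to q = |t| * sqrt(2)."""
    a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
    pair = tukey_hsd([group("a", a), group("b", b)])[0]
    t = t_test_unpaired(group("a", a), group("b", b))
    assert pair.p_value == pytest.approx(t.p_value, rel=1e-6)


# ---------------------------------------------------------------- Spearman

def test_spearman_perfect_monotone():
    up = spearman([1, 2, 3, 4], [10, 20, 30, 40])
    assert up.statistic == pytest.approx(1.0)
    down = spearman([1, 2, 3, 4], [4, 3, 2, 1])
    assert down.statistic == pytest.approx(-1.0)


def test_spearman_hand_computed_r():
    res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
    assert res.statistic == pytest.approx(0.8)


def test_spearman_undefined_with_constant_input():
    res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert math.isnan(res.statistic) and math.isnan(res.p_value)


@given(
    st.lists(st.floats(-100, 100, allow_nan=False), min_size=3, max_size=12),
    st.lists(st.floats(-100, 100, allow_nan=False), min_size=3, max_size=12),
)
def test_spearman_equals_pearson_on_ranks(x, y):
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return
    expected = sps.pearsonr(rx, ry).statistic
    assert spearman(x, y).statistic == pytest.approx(expected, abs=1e-9)


def test_spearman_exact_p_matches_full_enumeration_at_n6():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
    res = spearman(x, y)
    r_obs = abs(res.statistic)
    hits = sum(
        1
        for perm in itertools.permutations(range(1, 7))
        if abs(sps.pearsonr(x, perm).statistic) >= r_obs - 1e-12
    )
    assert res.p_value == pytest.approx(hits / math.factorial(6))
    assert "exact" in res.method
    assert 0.0 <= res.details["p_asymptotic"] <= 1.0


def test_spearman_large_n_uses_t_approximation():
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    y = x + rng.normal(scale=0.5, size=20)
    res = spearman(x, y)
    assert "t-approximation" in res.method
    assert res.p_value == pytest.approx(res.details["p_asymptotic"])
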