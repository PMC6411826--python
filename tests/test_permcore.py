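"""Permutation engine: enumeration oracles, classical-F agreement, maxT."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emonback.permcore import (
    PermConfig,
    maxt_adjust,
    mixed_anova_f,
    perm_mixed_anova,
    perm_signed_rank,
    perm_spearman,
    perm_spearman_diff,
    perm_spearman_family,
    perm_two_sample_t,
)


def cfg(R=500, seed=0, **kw):
    return PermConfig(n_reshuffles=R, seed=seed, **kw)


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracles (independent code paths via scipy statistics)
# ---------------------------------------------------------------------------

def oracle_two_sample(a, b):
    """p by brute-force relabeling over all C(n, na) group assignments."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(a) + len(b)
    t_obs = stats.ttest_ind(a, b, equal_var=True).statistic
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        sel = np.zeros(n, bool)
        sel[list(idx)] = True
        t = stats.ttest_ind(pooled[sel], pooled[~sel], equal_var=True).statistic
        count += abs(t) >= abs(t_obs) - 1e-12
        total += 1
    return count / total


def oracle_signed_rank(d):
    """p by brute force over all 2^n sign patterns (paired t statistic)."""
    n = len(d)
    t_obs = stats.ttest_1samp(d, 0.0).statistic
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        t = stats.ttest_1samp(np.array(signs) * d, 0.0).statistic
        count += abs(t) >= abs(t_obs) - 1e-12
    return count / 2**n


def oracle_spearman(x, y):
    """p by brute force over all n! pairings."""
    rho_obs = stats.spearmanr(x, y).statistic
    count = total = 0
    for perm in itertools.permutations(range(len(y))):
        rho = stats.spearmanr(x, y[list(perm)]).statistic
        count += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


def oracle_spearman_diff(xa, ya, xb, yb):
    """p by brute force over all group reassignments of the (x, y) pairs."""
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    na, n = len(xa), len(x)

    def delta(idx):
        sel = np.zeros(n, bool)
        sel[list(idx)] = True
        return (stats.spearmanr(x[sel], y[sel]).statistic
                - stats.spearmanr(x[~sel], y[~sel]).statistic)

    obs = delta(range(na))
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        count += abs(delta(idx)) >= abs(obs) - 1e-12
        total += 1
    return count / total


def test_two_sample_matches_enumeration(rng):
    a = rng.normal(0, 1, 4)
    b = rng.normal(1, 1, 3)
    res = perm_two_sample_t(a, b, cfg())
    assert res.exact
    assert len(res.null_distribution) == 35  # C(7,4)
    assert res.p_raw == pytest.approx(oracle_two_sample(a, b), abs=0)


def test_signed_rank_matches_enumeration(rng):
    x = rng.normal(0.5, 1, 8)
    y = rng.normal(0, 1, 8)
    res = perm_signed_rank(x, y, cfg())
    assert res.exact and len(res.null_distribution) == 256
    assert res.p_raw == pytest.approx(oracle_signed_rank(x - y), abs=0)


def test_spearman_matches_enumeration(rng):
    x = rng.normal(size=6)
    y = x + rng.normal(size=6)
    res = perm_spearman(x, y, cfg())
    assert res.exact and len(res.null_distribution) == 720
    assert res.p_raw == pytest.approx(oracle_spearman(x, y), abs=0)


def test_spearman_diff_matches_enumeration(rng):
    xa, ya = rng.normal(size=4), rng.normal(size=4)
    xb, yb = rng.normal(size=4), rng.normal(size=4)
    res = perm_spearman_diff(xa, ya, xb, yb, cfg())
    assert res.exact and len(res.null_distribution) == 70  # C(8,4)
    assert res.p_raw == pytest.approx(oracle_spearman_diff(xa, ya, xb, yb), abs=0)


# ---------------------------------------------------------------------------
# degenerate and extreme cases
# ---------------------------------------------------------------------------

def test_two_sample_identical_vectors_gives_zero_t_p_one():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    res = perm_two_sample_t(a, a.copy(), cfg())
    assert res.observed == pytest.approx(0.0)
    assert res.p_raw == pytest.approx(1.0)


def test_two_sample_constant_data_raises():
    with pytest.raises(ValueError, match="constant"):
        perm_two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0], cfg())


def test_two_sample_saturated_effect_hits_p_floor(rng):
    a = rng.normal(0, 1, 20)
    b = rng.normal(5, 1, 20)
    res = perm_two_sample_t(a, b, cfg(R=999, seed=3))
    assert not res.exact
    assert res.p_raw == pytest.approx(1.0 / (999 + 1))


def test_signed_rank_all_zero_differences_warns_p_one():
    x = np.arange(5.0)
    with pytest.warns(UserWarning, match="zero"):
        res = perm_signed_rank(x, x.copy(), cfg())
    assert res.p_raw == 1.0


def test_signed_rank_positive_differences_hit_enumeration_floor(rng):
    # 15 strictly positive differences: exact sign-flip space 2^15, the
    # two-sided p cannot go below 2/2^15
    x = rng.uniform(1, 2, 15)
    res = perm_signed_rank(x, np.zeros(15), cfg(R=10_000, seed=1))
    floor = 2.0 / 2**15
    assert res.p_raw <= 2.0 / (10_000 + 1) + floor


def test_wilcoxon_statistic_agrees_with_scipy_rank_sum(rng):
    x = rng.normal(1, 1, 12)
    y = rng.normal(0, 1, 12)
    res = perm_signed_rank(x, y, cfg(), statistic="wilcoxon")
    d = x - y
    n = len(d)
    w_plus = stats.wilcoxon(d, alternative="two-sided").statistic
    # scipy reports min(W+, W-); centred sum = W+ - W- = 2 W+/- - n(n+1)/2
    expected = n * (n + 1) / 2 - 2 * w_plus
    assert abs(res.observed) == pytest.approx(expected)


@pytest.mark.parametrize("ytrans,expected", [(lambda r: r**2, 1.0), (lambda r: -r, -1.0)])
def test_spearman_perfect_monotone(ytrans, expected):
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = perm_spearman(x, ytrans(x), cfg())
    assert res.observed == pytest.approx(expected)


def test_spearman_constant_input_raises():
    with pytest.raises(ValueError, match="constant|equal length"):
        perm_spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0], cfg())


def test_spearman_diff_bounds_and_exchangeability(rng):
    x = np.arange(5.0)
    res = perm_spearman_diff(x, x, x, -x, cfg())
    assert res.observed == pytest.approx(2.0)  # rho 1 minus rho -1
    xa = rng.normal(size=5)
    ya = rng.normal(size=5)
    res0 = perm_spearman_diff(xa, ya, xa.copy(), ya.copy(), cfg())
    assert res0.observed == pytest.approx(0.0)
    assert res0.p_raw > 0.9


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

def long_table(values, groups, conds=("c1", "c2", "c3")):
    rows = []
    for s, (row, g) in enumerate(zip(values, groups)):
        for c, v in zip(conds, row):
            rows.append({"subject": f"s{s}", "group": g, "condition": c, "value": v})
    return pd.DataFrame(rows)


@pytest.mark.parametrize("n_a,n_b", [(3, 3), (4, 3)])
def test_mixed_anova_f_matches_pingouin(rng, n_a, n_b):
    pingouin = pytest.importorskip("pingouin")
    n = n_a + n_b
    values = rng.normal(size=(n, 3)) + rng.normal(size=(n, 1))
    groups = ["a"] * n_a + ["b"] * n_b
    table = long_table(values, groups)
    f_b, f_c, f_i = mixed_anova_f(table)
    aov = pingouin.mixed_anova(table, dv="value", within="condition",
                               subject="subject", between="group")
    assert f_b == pytest.approx(aov.loc[aov.Source == "group", "F"].item(), rel=1e-9)
    assert f_c == pytest.approx(aov.loc[aov.Source == "condition", "F"].item(), rel=1e-9)
    assert f_i == pytest.approx(aov.loc[aov.Source == "Interaction", "F"].item(), rel=1e-9)


def test_mixed_anova_textbook_sums_of_squares(rng):
    # independent oracle: explicit SS decomposition on a balanced 6x3 table
    values = rng.normal(size=(6, 3))
    groups = np.array([0, 0, 0, 1, 1, 1])
    table = long_table(values, groups)
    f_b, f_c, f_i = mixed_anova_f(table)

    grand = values.mean()
    m_subj = values.mean(1)
    m_cond = values.mean(0)
    m_grp = np.array([values[groups == g].mean() for g in (0, 1)])
    cell = np.array([values[groups == g].mean(0) for g in (0, 1)])
    ss_b = 3 * 3 * ((m_grp - grand) ** 2).sum()
    ss_s = 3 * sum((m_subj[s] - m_grp[groups[s]]) ** 2 for s in range(6))
    ss_c = 6 * ((m_cond - grand) ** 2).sum()
    ss_i = 3 * ((cell - m_grp[:, None] - m_cond[None, :] + grand) ** 2).sum()
    ss_e = ((values - grand) ** 2).sum() - ss_b - ss_s - ss_c - ss_i
    assert f_b == pytest.approx((ss_b / 1) / (ss_s / 4), rel=1e-9)
    assert f_c == pytest.approx((ss_c / 2) / (ss_e / 8), rel=1e-9)
    assert f_i == pytest.approx((ss_i / 2) / (ss_e / 8), rel=1e-9)


def test_mixed_anova_no_within_variance_gives_zero_f():
    # identical values across conditions, groups differ by a constant
    values = np.tile([[1.0], [1.5], [2.0], [4.0], [4.5], [5.0]], (1, 3))
    table = long_table(values, ["a"] * 3 + ["b"] * 3)
    result = perm_mixed_anova(table, cfg(R=50))
    assert result["within"].observed == pytest.approx(0.0)
    assert result["between"].observed > 0


def test_mixed_anova_incomplete_design_raises(rng):
    table = long_table(rng.normal(size=(4, 3)), ["a", "a", "b", "b"])
    with pytest.raises(ValueError, match="incomplete"):
        perm_mixed_anova(table.iloc[:-1], cfg(R=10))


# ---------------------------------------------------------------------------
# maxT
# ---------------------------------------------------------------------------

def test_maxt_single_member_family_is_identity(rng):
    res = perm_two_sample_t(rng.normal(size=6), rng.normal(size=6), cfg(R=200))
    fam = maxt_adjust([res])
    assert fam.members[0].p_adjusted == pytest.approx(res.p_raw)


def test_maxt_adjusted_p_dominates_raw(rng):
    members = [perm_two_sample_t(rng.normal(size=8), rng.normal(size=8),
                                 cfg(R=300, seed=9)) for _ in range(5)]
    fam = maxt_adjust(members)
    for m in fam.members:
        assert m.p_adjusted >= m.p_raw - 1e-12
    assert len(fam.maxT_distribution) == len(members[0].null_distribution)


def test_maxt_rejects_incompatible_streams(rng):
    r1 = perm_two_sample_t(rng.normal(size=8), rng.normal(size=8), cfg(R=100, seed=1))
    r2 = perm_two_sample_t(rng.normal(size=8), rng.normal(size=8), cfg(R=100, seed=2))
    with pytest.raises(ValueError, match="incompatible"):
        maxt_adjust([r1, r2])


def test_spearman_family_matches_single_tests(rng):
    # the synchronized family must reproduce each pair's single-test p
    # when run with the same reshuffle stream
    X = rng.normal(size=(12, 2))
    Y = rng.normal(size=(12, 3))
    fam = perm_spearman_family(X, Y, cfg(R=400, seed=5))
    k = 0
    for j in range(2):
        for s in range(3):
            single = perm_spearman(X[:, j], Y[:, s], cfg(R=400, seed=5))
            assert fam.members[k].observed == pytest.approx(single.observed)
            assert fam.members[k].p_raw == pytest.approx(single.p_raw)
            k += 1


# ---------------------------------------------------------------------------
# shared properties
# ---------------------------------------------------------------------------

def test_p_value_range_and_determinism(rng):
    a, b = rng.normal(size=25), rng.normal(size=25)
    r1 = perm_two_sample_t(a, b, cfg(R=200, seed=7))
    r2 = perm_two_sample_t(a, b, cfg(R=200, seed=7))
    assert r1.p_raw == r2.p_raw
    assert np.array_equal(r1.null_distribution, r2.null_distribution)
    assert 1.0 / 201 <= r1.p_raw <= 1.0


# ---------------------------------------------------------------------------
# hypothesis properties
# ---------------------------------------------------------------------------

from hypothesis import assume, given, settings
from hypothesis import strategies as st

finite = st.floats(-50, 50, allow_nan=False)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(finite, min_size=3, max_size=6),
       st.lists(finite, min_size=3, max_size=6),
       st.integers(0, 2**20))
def test_p_estimator_always_valid(a, b, seed):
    a, b = np.asarray(a), np.asarray(b)
    assume(np.ptp(np.concatenate([a, b])) > 0)
    res = perm_two_sample_t(a, b, cfg(R=99, seed=seed))
    lower = 0.0 if res.exact else 1.0 / (res.n_reshuffles + 1)
    assert lower <= res.p_raw <= 1.0
    if res.exact:
        assert res.p_raw > 0  # observed arrangement counts itself


@settings(max_examples=20, deadline=None, derandomize=True)
@pytest.mark.filterwarnings("ignore::UserWarning")
@given(st.lists(finite, min_size=4, max_size=7).flatmap(
    lambda xs: st.tuples(st.just(xs), st.lists(finite, min_size=len(xs), max_size=len(xs)))))
def test_signed_rank_antisymmetric_in_pair_order(pair):
    x, y = (np.asarray(v) for v in pair)
    assume(np.any(x != y))
    fwd = perm_signed_rank(x, y, cfg())   # enumeration mode at n <= 7
    rev = perm_signed_rank(y, x, cfg())
    assert fwd.observed == pytest.approx(-rev.observed)
    assert fwd.p_raw == rev.p_raw


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.1, 40, allow_nan=False), min_size=5, max_size=5),
       st.integers(0, 2**20))
def test_spearman_invariant_under_monotone_transform(ys, seed):
    x = np.arange(5.0)
    y = np.asarray(ys)
    assume(np.ptp(y) > 0)
    raw = perm_spearman(x, y, cfg(seed=seed))
    mono = perm_spearman(x, np.log1p(y), cfg(seed=seed))
    assert raw.observed == pytest.approx(mono.observed)
    assert raw.p_raw == mono.p_raw
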