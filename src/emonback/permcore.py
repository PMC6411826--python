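"""Permutation-testing engine: statistics, reshuffling schemes, maxT correction.

Every test here follows the same recipe: compute an observed statistic,
rebuild it under R random reshuffles of the exchangeable units (group
labels, signs, pairings), and report

    p = (1 + #{|T_r| >= |T_obs|}) / (R + 1)

for the two-sided case.  The +1 convention counts the observed arrangement
as one realisation of the null and guarantees p in [1/(R+1), 1].  When the
full permutation space is small (<= ``enumeration_limit`` arrangements) the
tests switch to exhaustive enumeration and the p-value is exact:
p = #{|T_pi| >= |T_obs|} / #arrangements, the identity arrangement included.

Families of tests that share one permutation stream can be corrected for
multiple comparisons with the single-step maxT method: the per-reshuffle
maximum of |T| across the family forms the null for every member.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PermConfig",
    "PermResult",
    "FamilyResult",
    "perm_two_sample_t",
    "perm_mixed_anova",
    "perm_signed_rank",
    "perm_spearman",
    "perm_spearman_diff",
    "perm_spearman_family",
    "maxt_adjust",
    "mixed_anova_f",
]


@dataclass
class PermConfig:
    """Settings shared by all permutation tests.

    n_reshuffles : Monte-Carlo reshuffles R (ignored when the space is
        small enough to enumerate).
    seed : seed for the reshuffle stream; identical (data, config) always
        reproduce identical results.
    alpha : nominal familywise level, used only for reporting.
    two_sided : compare |T_r| against |T_obs| (one-sided mode compares
        signed values).
    enumeration_limit : switch to exhaustive enumeration whenever the
        number of distinct arrangements does not exceed this.
    """

    n_reshuffles: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    two_sided: bool = True
    enumeration_limit: int = 20_000

    def __post_init__(self) -> None:
        if self.n_reshuffles < 1:
            raise ValueError("n_reshuffles must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PermResult:
    """Observed statistic plus its permutation null."""

    statistic_name: str
    observed: float
    null_distribution: np.ndarray
    p_raw: float
    n_reshuffles: int
    seed: int
    exact: bool = False
    p_adjusted: float | None = None
    n_degenerate: int = 0

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "observed": float(self.observed),
            "p_raw": float(self.p_raw),
            "p_adjusted": None if self.p_adjusted is None else float(self.p_adjusted),
            "n_reshuffles": int(self.n_reshuffles),
            "seed": int(self.seed),
            "exact": bool(self.exact),
        }
        if self.n_degenerate:
            d["n_degenerate"] = int(self.n_degenerate)
        return d


@dataclass
class FamilyResult:
    """maxT-corrected family of tests sharing one permutation stream."""

    members: list[PermResult]
    maxT_distribution: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        for m in self.members:
            if m.p_adjusted is not None and m.p_adjusted < m.p_raw - 1e-12:
                raise ValueError("adjusted p below raw p; family is inconsistent")


def _pvalue(observed: float, null: np.ndarray, *, exact: bool, two_sided: bool) -> float:
    if two_sided:
        count = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    else:
        count = int(np.sum(null >= observed - 1e-12))
    if exact:
        return count / len(null)
    return (1 + count) / (len(null) + 1)


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# two-sample t
# ---------------------------------------------------------------------------

def _pooled_t(a_sum, a_sumsq, na, b_sum, b_sumsq, nb):
    """Pooled-variance two-sample t from sufficient statistics (vectorised)."""
    ma = a_sum / na
    mb = b_sum / nb
    ssa = a_sumsq - na * ma**2
    ssb = b_sumsq - nb * mb**2
    sp2 = (ssa + ssb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def perm_two_sample_t(a, b, config: PermConfig | None = None) -> PermResult:
    """Two-sample pooled-variance t with a group-label permutation null.

    The null reassigns the pooled observations to two groups of the
    original sizes.  Enumerates all C(na+nb, na) assignments when feasible.
    """
    config = config or PermConfig()
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("constant data: pooled variance is zero, t undefined")
    na, nb = len(a), len(b)
    n = na + nb
    total_sum = pooled.sum()
    total_sumsq = (pooled**2).sum()

    def t_from_a_indices(idx_matrix: np.ndarray) -> np.ndarray:
        a_sum = pooled[idx_matrix].sum(axis=1)
        a_sumsq = (pooled[idx_matrix] ** 2).sum(axis=1)
        return _pooled_t(a_sum, a_sumsq, na, total_sum - a_sum, total_sumsq - a_sumsq, nb)

    t_obs = float(t_from_a_indices(np.arange(na)[None, :])[0])

    n_arrangements = math.comb(n, na)
    if n_arrangements <= config.enumeration_limit:
        combos = np.array(list(itertools.combinations(range(n), na)))
        null = t_from_a_indices(combos)
        exact = True
    else:
        rng = config.rng()
        perms = np.array([rng.permutation(n)[:na] for _ in range(config.n_reshuffles)])
        null = t_from_a_indices(perms)
        exact = False

    p = _pvalue(t_obs, null, exact=exact, two_sided=config.two_sided)
    return PermResult("t-obs", t_obs, null, p, len(null), config.seed, exact=exact)


# ---------------------------------------------------------------------------
# mixed-design ANOVA
# ---------------------------------------------------------------------------

def _mixed_anova_f_from_matrix(values: np.ndarray, group_of_subject: np.ndarray):
    """Classical mixed-ANOVA F values from a subjects x conditions matrix.

    Between-subjects factor: group; within-subjects factor: condition.
    Error strata: subjects-within-group for the between effect and the
    condition x subject-within-group residual for the within and
    interaction effects.  Unequal group sizes use cell-mean (weighted)
    sums of squares.
    """
    n_subj, n_cond = values.shape
    groups = np.unique(group_of_subject)
    g = len(groups)
    grand = values.mean()

    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)

    ss_between = 0.0
    ss_subj = 0.0
    ss_inter = 0.0
    for gi in groups:
        sel = group_of_subject == gi
        ni = int(sel.sum())
        gm = values[sel].mean()
        ss_between += n_cond * ni * (gm - grand) ** 2
        ss_subj += n_cond * np.sum((subj_means[sel] - gm) ** 2)
        cellm = values[sel].mean(axis=0)  # group x condition cell means
        ss_inter += ni * np.sum((cellm - gm - cond_means + grand) ** 2)
    ss_cond = n_subj * np.sum((cond_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_between - ss_subj - ss_cond - ss_inter

    df_between = g - 1
    df_subj = n_subj - g
    df_cond = n_cond - 1
    df_inter = (g - 1) * (n_cond - 1)
    df_err = df_subj * df_cond

    def _f(ss_num, df_num, ss_den, df_den):
        denom = ss_den / df_den
        if denom <= 0:
            return 0.0
        return (ss_num / df_num) / denom

    f_between = _f(ss_between, df_between, ss_subj, df_subj)
    f_cond = _f(ss_cond, df_cond, ss_err, df_err)
    f_inter = _f(ss_inter, df_inter, ss_err, df_err)
    return f_between, f_cond, f_inter


def mixed_anova_f(table, subject="subject", group="group", condition="condition", value="value"):
    """Observed mixed-ANOVA F statistics from a long-format table.

    Returns (f_between, f_condition, f_interaction).  Requires a complete
    design: every subject observed in every condition exactly once.
    """
    values, group_of_subject, _, _ = _long_to_matrix(table, subject, group, condition, value)
    return _mixed_anova_f_from_matrix(values, group_of_subject)


def _long_to_matrix(table, subject, group, condition, value):
    import pandas as pd

    df = pd.DataFrame(table)
    pivot = df.pivot_table(index=subject, columns=condition, values=value, aggfunc="mean")
    counts = df.groupby([subject, condition]).size().unstack(fill_value=0)
    if (counts != 1).any().any():
        missing = [
            (s, c)
            for s in counts.index
            for c in counts.columns
            if counts.loc[s, c] != 1
        ]
        raise ValueError(f"design incomplete or duplicated in cells: {missing[:10]}")
    gmap = df.groupby(subject)[group].agg(lambda s: s.iloc[0])
    gmap = gmap.loc[pivot.index]
    codes, uniques = gmap.factorize()
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups")
    if np.min(np.bincount(codes)) < 2:
        raise ValueError("need at least 2 subjects per group")
    return pivot.to_numpy(dtype=float), codes, list(pivot.index), list(pivot.columns)


def perm_mixed_anova(table, config: PermConfig | None = None, *, subject="subject",
                     group="group", condition="condition", value="value") -> dict:
    """Permutation mixed ANOVA: group (between), condition (within), interaction.

    Null construction (Manly-style raw-label reshuffling per stratum):

    - between: permute group labels across subjects;
    - within and interaction: permute condition labels independently
      within each subject.

    Returns ``{"between": PermResult, "within": PermResult,
    "interaction": PermResult}``.
    """
    config = config or PermConfig()
    values, codes, _, _ = _long_to_matrix(table, subject, group, condition, value)
    n_subj, n_cond = values.shape

    f_b, f_c, f_i = _mixed_anova_f_from_matrix(values, codes)

    rng = config.rng()
    R = config.n_reshuffles
    null_b = np.empty(R)
    null_c = np.empty(R)
    null_i = np.empty(R)
    for r in range(R):
        perm_codes = rng.permutation(codes)
        null_b[r], _, _ = _mixed_anova_f_from_matrix(values, perm_codes)
        shuffled = values.copy()
        for s in range(n_subj):
            shuffled[s] = shuffled[s][rng.permutation(n_cond)]
        _, null_c[r], null_i[r] = _mixed_anova_f_from_matrix(shuffled, codes)

    out = {}
    for name, obs, null in [
        ("between", f_b, null_b),
        ("within", f_c, null_c),
        ("interaction", f_i, null_i),
    ]:
        # F is non-negative; the two-sided/one-sided distinction collapses.
        p = _pvalue(obs, null, exact=False, two_sided=False)
        out[name] = PermResult(f"F-obs ({name})", float(obs), null, p, R, config.seed)
    return out


# ---------------------------------------------------------------------------
# signed-rank / sign-flip paired test
# ---------------------------------------------------------------------------

def perm_signed_rank(x, y, config: PermConfig | None = None, *, statistic: str = "t") -> PermResult:
    """Paired two-sample test with a sign-flipping null.

    Differences d = x - y (zeros dropped) are tested for symmetry about 0
    by random independent sign flips.  ``statistic="t"`` (default) reports
    the paired t on the differences -- the scale group comparisons are
    conventionally reported on -- while ``statistic="wilcoxon"`` uses the
    centred signed-rank sum.  Both share the same distribution-free null.
    Enumerates all 2^n sign patterns when feasible.
    """
    config = config or PermConfig()
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must be paired vectors of equal length >= 2")
    d = x - y
    d = d[d != 0]
    if len(d) < 2:
        # no information after dropping zeros (t needs >= 2 differences)
        warnings.warn("fewer than 2 nonzero paired differences; returning p = 1",
                      stacklevel=2)
        return PermResult("t-obs", 0.0, np.zeros(1), 1.0, 1, config.seed, exact=True)

    n = len(d)
    if statistic == "t":
        vals = d
    elif statistic == "wilcoxon":
        # centred signed-rank sum: sum of ranks of |d| carrying d's sign
        vals = np.sign(d) * stats.rankdata(np.abs(d))
    else:
        raise ValueError("statistic must be 't' or 'wilcoxon'")

    def stat_for_signs(signs: np.ndarray) -> np.ndarray:
        flipped = signs * vals[None, :]
        if statistic == "t":
            m = flipped.mean(axis=1)
            sd = flipped.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
        return flipped.sum(axis=1)

    t_obs = float(stat_for_signs(np.ones((1, n)))[0])

    if 2**n <= config.enumeration_limit:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        null = stat_for_signs(signs)
        exact = True
    else:
        rng = config.rng()
        signs = rng.choice([1.0, -1.0], size=(config.n_reshuffles, n))
        null = stat_for_signs(signs)
        exact = False

    name = "t-obs" if statistic == "t" else "W-obs"
    p = _pvalue(t_obs, null, exact=exact, two_sided=config.two_sided)
    return PermResult(name, t_obs, null, p, len(null), config.seed, exact=exact)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _spearman_rho(x_rank: np.ndarray, y_rank: np.ndarray) -> float:
    """Pearson correlation of midranks (ties handled by midranks)."""
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    return float((xc * yc).sum() / denom)


def perm_spearman(x, y, config: PermConfig | None = None) -> PermResult:
    """Spearman's rho with a pairing-permutation null.

    y is permuted against fixed x; enumerates all n! pairings when
    feasible.  Ties receive midranks.
    """
    config = config or PermConfig()
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho_obs = _spearman_rho(xr, yr)

    n = len(x)
    if math.factorial(n) <= config.enumeration_limit:
        perms = np.array(list(itertools.permutations(range(n))))
        exact = True
    else:
        rng = config.rng()
        perms = np.array([rng.permutation(n) for _ in range(config.n_reshuffles)])
        exact = False

    xc = xr - xr.mean()
    ycs = yr[perms] - yr.mean()
    denom = np.sqrt((xc**2).sum() * (ycs**2).sum(axis=1))
    null = (ycs @ xc) / denom

    p = _pvalue(rho_obs, null, exact=exact, two_sided=config.two_sided)
    return PermResult("rho", rho_obs, null, p, len(null), config.seed, exact=exact)


def perm_spearman_diff(x_a, y_a, x_b, y_b, config: PermConfig | None = None) -> PermResult:
    """Between-group difference of Spearman correlations, Delta-rho = rho_a - rho_b.

    The null reassigns the (x, y) pairs to the two groups (sizes
    preserved) and recomputes Delta-rho, re-ranking within each permuted
    group.  A permuted group with a constant vector contributes
    Delta-rho = 0 for that reshuffle; the count of such degenerate
    reshuffles is reported in ``n_degenerate``.
    """
    config = config or PermConfig()
    x_a, y_a = _as_1d(x_a, "x_a"), _as_1d(y_a, "y_a")
    x_b, y_b = _as_1d(x_b, "x_b"), _as_1d(y_b, "y_b")
    if len(x_a) != len(y_a) or len(x_b) != len(y_b):
        raise ValueError("x and y must be paired within each group")
    if len(x_a) < 3 or len(x_b) < 3:
        raise ValueError("need at least 3 pairs per group")

    x = np.concatenate([x_a, x_b])
    y = np.concatenate([y_a, y_b])
    na = len(x_a)
    n = len(x)
    degenerate = 0

    def delta_rho(idx_a: np.ndarray) -> float:
        nonlocal degenerate
        in_a = np.zeros(n, dtype=bool)
        in_a[idx_a] = True
        try:
            ra = _spearman_rho(stats.rankdata(x[in_a]), stats.rankdata(y[in_a]))
            rb = _spearman_rho(stats.rankdata(x[~in_a]), stats.rankdata(y[~in_a]))
        except ValueError:
            degenerate += 1
            return 0.0
        return ra - rb

    obs = delta_rho(np.arange(na))

    n_arrangements = math.comb(n, na)
    if n_arrangements <= config.enumeration_limit:
        null = np.array([delta_rho(np.array(c)) for c in itertools.combinations(range(n), na)])
        exact = True
    else:
        rng = config.rng()
        null = np.array([delta_rho(rng.permutation(n)[:na]) for _ in range(config.n_reshuffles)])
        exact = False

    p = _pvalue(obs, null, exact=exact, two_sided=config.two_sided)
    return PermResult("delta-rho", obs, null, p, len(null), config.seed,
                      exact=exact, n_degenerate=degenerate)


def perm_spearman_family(x_matrix, y_matrix, config: PermConfig | None = None,
                         pair_names: list | None = None) -> FamilyResult:
    """Spearman tests for every (column of x) x (column of y) pair under one
    synchronized permutation stream, maxT-corrected.

    One subject permutation per reshuffle is applied to all y columns, so
    the per-reshuffle maximum |rho| over the family is exchangeable with
    the observed values -- the single-step maxT construction.
    """
    config = config or PermConfig()
    X = np.atleast_2d(np.asarray(x_matrix, dtype=float))
    Y = np.atleast_2d(np.asarray(y_matrix, dtype=float))
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("x_matrix and y_matrix must share the subject dimension")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")

    Xr = np.apply_along_axis(stats.rankdata, 0, X)
    Yr = np.apply_along_axis(stats.rankdata, 0, Y)
    Xc = Xr - Xr.mean(axis=0)
    Yc = Yr - Yr.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    if np.any(sx == 0) or np.any(sy == 0):
        raise ValueError("constant column: Spearman rho undefined")

    obs = (Xc.T @ Yc) / np.outer(sx, sy)  # p x q observed rho matrix

    if math.factorial(n) <= config.enumeration_limit:
        perms = np.array(list(itertools.permutations(range(n))))
        exact = True
    else:
        rng = config.rng()
        perms = np.array([rng.permutation(n) for _ in range(config.n_reshuffles)])
        exact = False
    R = len(perms)

    p_cols, q_cols = obs.shape
    null = np.empty((R, p_cols, q_cols))
    for r, perm in enumerate(perms):
        null[r] = (Xc.T @ Yc[perm]) / np.outer(sx, sy)

    flat_obs = obs.ravel()
    flat_null = null.reshape(R, -1)
    members = []
    names = pair_names or [f"pair_{i}" for i in range(flat_obs.size)]
    for i, name in enumerate(names):
        p_raw = _pvalue(flat_obs[i], flat_null[:, i], exact=exact, two_sided=config.two_sided)
        members.append(PermResult(f"rho ({name})", float(flat_obs[i]), flat_null[:, i],
                                  p_raw, R, config.seed, exact=exact))
    fam = maxt_adjust(members)
    return fam


# ---------------------------------------------------------------------------
# maxT
# ---------------------------------------------------------------------------

def maxt_adjust(members: list[PermResult]) -> FamilyResult:
    """Single-step maxT familywise correction over a synchronized family.

    Members must share one permutation stream (same scheme, R and seed), so
    that reshuffle r of one member is the same reshuffle of every other.
    The per-reshuffle maximum of |T| across members is the familywise null;
    each member's adjusted p counts how often that maximum reaches its own
    |observed|.  Statistics entering one family must be on a common scale
    (all t, or all rho): maxT exchangeability fails across mixed scales.
    """
    if not members:
        raise ValueError("empty family")
    R = members[0].n_reshuffles
    exact = members[0].exact
    seed = members[0].seed
    for m in members:
        if m.n_reshuffles != R or m.exact != exact or m.seed != seed:
            raise ValueError("family members use incompatible permutation streams")

    nulls = np.stack([np.abs(m.null_distribution) for m in members])
    maxt = nulls.max(axis=0)
    for m in members:
        count = int(np.sum(maxt >= abs(m.observed) - 1e-12))
        p_adj = count / R if exact else (1 + count) / (R + 1)
        m.p_adjusted = max(p_adj, m.p_raw)
    return FamilyResult(members=members, maxT_distribution=maxt)
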