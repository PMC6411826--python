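"""Inclusion screening on DASS-21 depression scores and demographic group tests.

Controls are retained only below a "mild" depression rating and depressed
participants only at or above a "moderate" rating, leaving a deliberate
gap (scores 12-13) that neither group accepts.  Group comparability is
then checked with a two-sided Fisher's exact test on sex and permutation
t-tests on age and the DASS-21 subscales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .permcore import PermConfig, PermResult, perm_two_sample_t

__all__ = [
    "ScreeningConfig",
    "apply_screening",
    "fisher_exact_2x2",
    "compare_groups_continuous",
    "screening_report",
]


@dataclass
class ScreeningConfig:
    """DASS-21 depression-subscale cut-offs.

    control_max_depression : exclusive upper bound for control inclusion
        (a control scoring at or above this is excluded; default 12, the
        "mild" rating).
    depressed_min_depression : inclusive lower bound for depressed-group
        inclusion (default 14, the "moderate" rating).
    """

    control_max_depression: int = 12
    depressed_min_depression: int = 14

    def __post_init__(self) -> None:
        if self.control_max_depression < 0 or self.depressed_min_depression < 0:
            raise ValueError("thresholds must be >= 0")


def apply_screening(cohort: pd.DataFrame,
                    config: ScreeningConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into (included, excluded) by depression score.

    Controls are kept iff dass_depression < control_max_depression;
    depressed participants iff dass_depression >= depressed_min_depression.
    The two frames partition the input (disjoint, union = cohort).
    """
    config = config or ScreeningConfig()
    required = {"group", "dass_depression"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort missing columns: {sorted(required - set(cohort.columns))}")
    bad = cohort[cohort["dass_depression"].isna()]
    if len(bad):
        ids = bad.get("subject_id", bad.index).tolist()
        raise ValueError(f"missing dass_depression for subjects: {ids}")

    is_control = cohort["group"] == "control"
    keep = np.where(
        is_control,
        cohort["dass_depression"] < config.control_max_depression,
        cohort["dass_depression"] >= config.depressed_min_depression,
    )
    included = cohort[keep].copy()
    excluded = cohort[~keep].copy()
    included["included"] = True
    excluded["included"] = False
    return included, excluded


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p).  The odds ratio is the sample ratio
    (a*d)/(b*c) (inf if b*c == 0 with a*d > 0); the two-sided p sums the
    hypergeometric probabilities, at fixed margins, of every table whose
    point probability does not exceed the observed table's.
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0):
        raise ValueError("negative cell count")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def compare_groups_continuous(values_a, values_b, config: PermConfig | None = None) -> PermResult:
    """Permutation two-sample t comparison of a continuous measure.

    Thin wrapper over the permutation engine, used for age and the
    DASS-21 subscales.
    """
    return perm_two_sample_t(values_a, values_b, config)


def screening_report(included: pd.DataFrame, excluded: pd.DataFrame,
                     config: ScreeningConfig) -> dict:
    """Per-subject screening decisions with reasons, as a JSON-able dict."""
    decisions = []
    for df, kept in [(included, True), (excluded, False)]:
        for _, row in df.iterrows():
            if row["group"] == "control":
                rule = f"dass_depression < {config.control_max_depression}"
            else:
                rule = f"dass_depression >= {config.depressed_min_depression}"
            decisions.append({
                "subject_id": str(row.get("subject_id", "")),
                "group": str(row["group"]),
                "dass_depression": int(row["dass_depression"]),
                "included": kept,
                "rule": rule,
            })
    report = {
        "config": {
            "control_max_depression": config.control_max_depression,
            "depressed_min_depression": config.depressed_min_depression,
        },
        "n_included": int(len(included)),
        "n_excluded": int(len(excluded)),
        "decisions": decisions,
    }
    # round-trip check: the report must be serialisable as produced
    json.dumps(report)
    return report
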