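"""Clinical-fMRI association stage.

Within each group, every significant cluster's per-subject mean contrast
estimate is rank-correlated (Spearman) with each DASS-21 subscale under a
permutation null; the full cluster x scale family shares one permutation
stream and is corrected single-step maxT.  Between groups, the
difference of correlations Delta-rho = rho_a - rho_b is tested by
reassigning subjects to groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .permcore import FamilyResult, PermConfig, PermResult, perm_spearman_diff, perm_spearman_family
from .synthio import DASS_SCALES

__all__ = ["correlate_clusters_clinical", "compare_group_correlations", "association_frame"]


def _group_arrays(cluster_means: pd.DataFrame, clinical: pd.DataFrame,
                  group: str, scales) -> tuple[np.ndarray, np.ndarray, list]:
    """Align cluster-mean and clinical rows for one group by subject_id."""
    clin = clinical[clinical["group"] == group]
    merged = cluster_means.merge(clin, on="subject_id", suffixes=("", "_clin"))
    if len(merged) < 3:
        raise ValueError(f"fewer than 3 subjects in group {group!r}")
    cluster_cols = [c for c in cluster_means.columns if c != "subject_id"]
    for s in scales:
        if merged[s].isna().any():
            raise ValueError(f"missing {s} scores in group {group!r}")
    X = merged[cluster_cols].to_numpy(dtype=float)
    Y = merged[list(scales)].to_numpy(dtype=float)
    return X, Y, cluster_cols


def correlate_clusters_clinical(cluster_means: pd.DataFrame, clinical: pd.DataFrame,
                                group: str, config: PermConfig | None = None,
                                scales=DASS_SCALES) -> FamilyResult:
    """Per-group Spearman correlations over the cluster x scale family.

    ``cluster_means`` has a subject_id column plus one column per
    cluster; ``clinical`` is a cohort table.  Constant cluster columns
    are dropped with a warning (rho undefined).  Only the named group's
    rows are read.  All pairs share one synchronized permutation stream,
    so the returned family carries maxT-adjusted p-values.
    """
    import warnings

    config = config or PermConfig()
    X, Y, cluster_cols = _group_arrays(cluster_means, clinical, group, scales)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    keep_s = [k for k in range(Y.shape[1]) if np.ptp(Y[:, k]) > 0]
    skipped = ([cluster_cols[j] for j in range(X.shape[1]) if j not in keep]
               + [scales[k] for k in range(Y.shape[1]) if k not in keep_s])
    if skipped:
        warnings.warn(f"constant columns skipped (rho undefined): {skipped}", stacklevel=2)
    if not keep or not keep_s:
        raise ValueError("no non-constant (cluster, scale) pairs to test")
    names = [f"{cluster_cols[j]}~{scales[k]}" for j in keep for k in keep_s]
    return perm_spearman_family(X[:, keep], Y[:, keep_s], config, pair_names=names)


def compare_group_correlations(cluster_means: pd.DataFrame, clinical: pd.DataFrame,
                               group_a: str, group_b: str,
                               config: PermConfig | None = None,
                               scales=DASS_SCALES) -> dict[str, PermResult]:
    """Delta-rho (group_a minus group_b) per (cluster, scale) pair.

    Raw two-tailed p-values are reported per pair (the conventional
    report for correlation-difference follow-ups); apply
    :func:`emonback.permcore.maxt_adjust` to the values for a
    family-corrected view.
    """
    config = config or PermConfig()
    Xa, Ya, cluster_cols = _group_arrays(cluster_means, clinical, group_a, scales)
    Xb, Yb, _ = _group_arrays(cluster_means, clinical, group_b, scales)
    out = {}
    for j, cname in enumerate(cluster_cols):
        for k, s in enumerate(scales):
            res = perm_spearman_diff(Xa[:, j], Ya[:, k], Xb[:, j], Yb[:, k], config)
            out[f"{cname}~{s}"] = res
    return out


def association_frame(family: FamilyResult, delta: dict[str, PermResult] | None = None) -> pd.DataFrame:
    """Tabular view of an association family (one row per pair)."""
    rows = []
    for m in family.members:
        pair = m.statistic_name.removeprefix("rho (").removesuffix(")")
        row = {
            "pair": pair,
            "rho": m.observed,
            "p_raw": m.p_raw,
            "p_maxt": m.p_adjusted,
        }
        if delta and pair in delta:
            row["delta_rho"] = delta[pair].observed
            row["delta_p_raw"] = delta[pair].p_raw
        rows.append(row)
    return pd.DataFrame(rows)
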