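"""Group-level voxelwise permutation inference with TFCE and maxT FWE control.

A subject-by-voxel stack of contrast estimates is summarised by a
voxelwise t map, enhanced with threshold-free cluster enhancement (TFCE),
and referred to a permutation null (sign flips for one-sample, group-label
reshuffles for two-sample).  Familywise error is controlled single-step:
each voxel's corrected p counts how often the permutation maximum of the
enhanced map anywhere in the brain reaches that voxel's observed value.
Significant voxels are then grouped into connected clusters and
per-subject cluster means extracted for brain-behavior correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _tfce
from .permcore import PermConfig

__all__ = [
    "TFCEParams",
    "tfce_transform",
    "perm_one_sample",
    "perm_two_sample",
    "significant_clusters",
    "extract_cluster_means",
    "dice",
]


@dataclass
class TFCEParams:
    """TFCE settings: extent exponent E, height exponent H, threshold step
    dh (None = max statistic / n_steps, recomputed per map) and cluster
    connectivity (6 faces, 18 +edges, 26 +corners)."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _tfce_positive(values: np.ndarray, params: TFCEParams) -> np.ndarray:
    """TFCE of the positive part of a 3D map.

    Integrates e(h)^E h^H dh over thresholds h, where e(h) is the size of
    the connected supra-threshold component containing each voxel at
    threshold h.  Midpoint heights are used for the discrete sum, which
    converges to the continuous integral as dh -> 0.  The default path is
    an incremental union-find sweep (one voxel insertion per voxel);
    without numba it falls back to relabeling every threshold.
    """
    pos = np.where(values > 0, values, 0.0)
    vmax = pos.max()
    out = np.zeros_like(pos)
    if vmax <= 0:
        return out
    dh = params.dh if params.dh is not None else vmax / params.n_steps
    n_thresh = int(np.floor(vmax / dh + 1e-9))
    if _tfce.HAVE_NUMBA:
        return _tfce.tfce_positive_fast(pos, params.E, params.H, dh, n_thresh,
                                        params.connectivity)
    struct = _STRUCTS[params.connectivity]
    for k in range(1, n_thresh + 1):
        h = k * dh
        supra = pos >= h
        labels, n = ndimage.label(supra, structure=struct)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        extent = sizes[labels]
        h_mid = h - dh / 2.0  # midpoint height: the discrete sum tracks the integral
        out[supra] += (extent[supra] ** params.E) * (h_mid**params.H) * dh
    return out


def tfce_transform(values: np.ndarray, mask: np.ndarray | None = None,
                   params: TFCEParams | None = None) -> np.ndarray:
    """Signed TFCE of a 3D statistic map.

    Positive and negative parts are enhanced separately (second pass on
    the negated map) and recombined with their signs, so directional
    contrasts keep their direction.
    """
    params = params or TFCEParams()
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("expected a 3D statistic map")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        values = np.where(mask, values, 0.0)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values inside the mask")
    return _tfce_positive(values, params) - _tfce_positive(-values, params)


# ---------------------------------------------------------------------------
# t statistics on subject stacks
# ---------------------------------------------------------------------------

def _one_sample_t(stack: np.ndarray) -> np.ndarray:
    n = stack.shape[0]
    m = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def _two_sample_t(stack: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    na = int(is_a.sum())
    nb = len(is_a) - na
    a = stack[is_a]
    b = stack[~is_a]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def _perm_tfce_fwe(mask: np.ndarray, stat_fn, perm_fn, config: PermConfig,
                   tfce: TFCEParams):
    """Shared engine: observed map, permutation maxima, voxelwise FWE p.

    stat_fn(stack_or_signs) -> 3D t map for one arrangement;
    perm_fn(rng) -> the argument for the next permuted arrangement.
    """
    t_obs = stat_fn(None)
    if np.any((t_obs == 0) & mask):
        n_flat = int(np.sum((t_obs == 0) & mask))
        warnings.warn(f"{n_flat} zero-variance voxels: t set to 0 there", stacklevel=3)
    tfce_obs = tfce_transform(t_obs, mask, tfce)

    rng = config.rng()
    R = config.n_reshuffles
    max_null = np.empty(R)
    for r in range(R):
        t_perm = stat_fn(perm_fn(rng))
        tfce_perm = tfce_transform(t_perm, mask, tfce)
        max_null[r] = np.abs(tfce_perm[mask]).max()

    abs_obs = np.abs(tfce_obs)
    # vectorised counting: for each voxel, #{r: max_null_r >= |tfce_obs|}
    sorted_null = np.sort(max_null)
    counts = R - np.searchsorted(sorted_null, abs_obs[mask] - 1e-12, side="left")
    fwe = np.ones(mask.shape)
    fwe[mask] = (1 + counts) / (R + 1)
    return t_obs, tfce_obs, fwe, max_null


def perm_one_sample(copes: np.ndarray, mask: np.ndarray,
                    config: PermConfig | None = None,
                    tfce: TFCEParams | None = None):
    """One-sample (pooled activation) TFCE permutation test.

    ``copes`` is (n_subjects, x, y, z).  The null randomly sign-flips
    each subject's whole map, exploiting symmetry of the no-activation
    null.  Returns (t map, TFCE map, voxelwise FWE p map, max-null).
    """
    config = config or PermConfig()
    tfce = tfce or TFCEParams()
    copes = np.asarray(copes, dtype=float)
    if copes.ndim != 4 or copes.shape[0] < 3:
        raise ValueError("need a (n_subjects >= 3, x, y, z) stack")
    mask = np.asarray(mask, dtype=bool)
    n = copes.shape[0]

    def stat_fn(signs):
        if signs is None:
            return _one_sample_t(copes)
        return _one_sample_t(copes * signs[:, None, None, None])

    def perm_fn(rng):
        return rng.choice([1.0, -1.0], size=n)

    return _perm_tfce_fwe(mask, stat_fn, perm_fn, config, tfce)


def perm_two_sample(copes_a: np.ndarray, copes_b: np.ndarray, mask: np.ndarray,
                    config: PermConfig | None = None,
                    tfce: TFCEParams | None = None):
    """Two-sample (a minus b) TFCE permutation test with group-label nulls.

    Returns (t map, TFCE map, voxelwise FWE p map, max-null).  The t map
    is signed (a > b positive); negate the inputs' order for the reverse
    direction — the permutation machinery is antisymmetric.
    """
    config = config or PermConfig()
    tfce = tfce or TFCEParams()
    copes_a = np.asarray(copes_a, dtype=float)
    copes_b = np.asarray(copes_b, dtype=float)
    if copes_a.ndim != 4 or copes_b.ndim != 4 or copes_a.shape[0] < 2 or copes_b.shape[0] < 2:
        raise ValueError("need (n >= 2, x, y, z) stacks for both groups")
    mask = np.asarray(mask, dtype=bool)
    stack = np.concatenate([copes_a, copes_b], axis=0)
    n = stack.shape[0]
    na = copes_a.shape[0]
    obs_assign = np.zeros(n, dtype=bool)
    obs_assign[:na] = True

    def stat_fn(assign):
        if assign is None:
            assign = obs_assign
        return _two_sample_t(stack, assign)

    def perm_fn(rng):
        assign = np.zeros(n, dtype=bool)
        assign[rng.permutation(n)[:na]] = True
        return assign

    return _perm_tfce_fwe(mask, stat_fn, perm_fn, config, tfce)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def significant_clusters(fwe_p: np.ndarray, stat_map: np.ndarray,
                         alpha: float = 0.05, connectivity: int = 26,
                         voxel_dims: tuple = (3.0, 3.0, 3.0)) -> tuple[pd.DataFrame, np.ndarray]:
    """Label connected components of the FWE-significant voxels.

    Returns (table, label volume).  The table has one row per cluster:
    label, size (voxels), peak voxel indices (0-based) and mm
    coordinates, peak statistic, and the cluster's minimum FWE p.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    fwe_p = np.asarray(fwe_p, dtype=float)
    stat_map = np.asarray(stat_map, dtype=float)
    supra = fwe_p <= alpha
    labels, n = ndimage.label(supra, structure=_STRUCTS[connectivity])
    rows = []
    for lab in range(1, n + 1):
        sel = labels == lab
        stats_here = np.where(sel, np.abs(stat_map), -np.inf)
        peak_idx = np.unravel_index(np.argmax(stats_here), stat_map.shape)
        rows.append({
            "label": lab,
            "size_voxels": int(sel.sum()),
            "peak_i": int(peak_idx[0]),
            "peak_j": int(peak_idx[1]),
            "peak_k": int(peak_idx[2]),
            "peak_x_mm": float(peak_idx[0] * voxel_dims[0]),
            "peak_y_mm": float(peak_idx[1] * voxel_dims[1]),
            "peak_z_mm": float(peak_idx[2] * voxel_dims[2]),
            "peak_stat": float(stat_map[peak_idx]),
            "min_fwe_p": float(fwe_p[sel].min()),
        })
    table = pd.DataFrame(rows, columns=[
        "label", "size_voxels", "peak_i", "peak_j", "peak_k",
        "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat", "min_fwe_p",
    ])
    return table, labels


def extract_cluster_means(labels: np.ndarray, cluster_ids, copes: np.ndarray) -> np.ndarray:
    """Mean contrast estimate per subject within each cluster.

    ``copes`` is (n_subjects, x, y, z); returns (n_subjects, n_clusters).
    """
    copes = np.asarray(copes, dtype=float)
    out = np.empty((copes.shape[0], len(cluster_ids)))
    for j, cid in enumerate(cluster_ids):
        sel = labels == cid
        if not sel.any():
            raise ValueError(f"cluster {cid} is empty")
        out[:, j] = copes[:, sel].mean(axis=1)
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
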