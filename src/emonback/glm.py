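"""First-level GLM: HRF, design matrices, preprocessing, fits and contrasts.

The task is a block design: each condition's on/off boxcar is convolved
with a canonical double-gamma hemodynamic response function and sampled at
volume acquisition times, optionally with temporal-derivative columns.
Per-voxel ordinary least squares yields condition amplitudes; emotion
conditions are contrasted against the mean of the pattern conditions, and
the two runs are pooled by inverse-variance fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "GLMFit",
    "ContrastSpec",
    "CopePair",
    "double_gamma_hrf",
    "build_design",
    "highpass_filter",
    "smooth_volume",
    "fit_glm",
    "emotion_contrast",
    "compute_cope",
    "fixed_effects_combine",
]

EMOTION_CONDITIONS = ("happy", "sad", "neutral")
PATTERN_CONDITIONS = ("vertical", "horizontal", "checked")
TASK_CONDITIONS = EMOTION_CONDITIONS + PATTERN_CONDITIONS


@dataclass
class HRFParams:
    """Canonical double-gamma HRF: a gamma-shaped peak at ~6 s minus a
    scaled gamma-shaped undershoot at ~16 s (SPM/FSL convention).

    All times in seconds.  peak_undershoot_ratio is the peak:undershoot
    amplitude ratio (undershoot weight = 1/ratio).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "peak_undershoot_ratio", "kernel_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def double_gamma_hrf(tr: float, params: HRFParams | None = None,
                     oversample: int = 1) -> np.ndarray:
    """Sample the double-gamma HRF at spacing tr/oversample over kernel_length.

    Shape/scale parameterisation: shape = delay/dispersion, scale =
    dispersion, so the gamma density peaks at delay - dispersion.  The
    kernel is scaled to unit peak.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    params = params or HRFParams()
    dt = tr / oversample
    t = np.arange(0, params.kernel_length + dt / 2, dt)
    peak = stats.gamma.pdf(t, params.peak_delay / params.peak_dispersion,
                           scale=params.peak_dispersion)
    under = stats.gamma.pdf(t, params.undershoot_delay / params.undershoot_dispersion,
                            scale=params.undershoot_dispersion)
    h = peak - under / params.peak_undershoot_ratio
    return h / h.max()


@dataclass
class DesignMatrix:
    """n_volumes x n_regressors matrix with labelled columns.

    Labels are condition names; derivative columns carry a
    "_derivative" suffix.  Rest/fixation is the implicit baseline.
    """

    matrix: np.ndarray
    labels: list[str]
    tr: float
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count does not match design columns")
        if np.any(np.all(self.matrix == 0, axis=0)):
            raise ValueError("design contains an all-zero column")

    @property
    def main_labels(self) -> list[str]:
        return [l for l in self.labels if not l.endswith("_derivative")]


def build_design(paradigm, run_index: int, n_volumes: int, tr: float,
                 hrf_params: HRFParams | None = None,
                 include_derivatives: bool = True,
                 oversample: int = 10) -> DesignMatrix:
    """Convolve each condition's block boxcar with the HRF and sample at TRs.

    The boxcar lives on a fine grid (spacing tr/oversample); discrete
    convolution with the HRF sampled on the same grid, scaled by the grid
    spacing, approximates the continuous convolution.  Temporal
    derivatives are backward first differences of the sampled regressor,
    zero at the first volume.  Conditions with no blocks in this run are
    dropped with a warning and recorded in ``dropped``.
    """
    run = paradigm.runs[run_index]
    duration_s = n_volumes * tr
    last_offset = max((b.onset + b.duration for b in run.blocks), default=0.0)
    if last_offset > duration_s + 1e-9:
        raise ValueError("paradigm run extends beyond the scan duration")

    params = hrf_params or HRFParams()
    dt = tr / oversample
    n_fine = int(round(duration_s / dt))
    hrf = double_gamma_hrf(tr, params, oversample=oversample)

    conditions = [c for c in TASK_CONDITIONS if any(b.condition == c for b in run.blocks)]
    dropped = [c for c in TASK_CONDITIONS if c not in conditions]
    if dropped:
        warnings.warn(f"conditions with no blocks in run {run_index}: {dropped}", stacklevel=2)

    cols, labels = [], []
    vol_idx = (np.arange(n_volumes) * oversample).astype(int)
    for cond in conditions:
        boxcar = np.zeros(n_fine)
        for b in run.blocks:
            if b.condition != cond:
                continue
            i0 = int(round(b.onset / dt))
            i1 = int(round((b.onset + b.duration) / dt))
            boxcar[i0:i1] = 1.0
        reg_fine = np.convolve(boxcar, hrf)[:n_fine] * dt
        reg = reg_fine[vol_idx]
        cols.append(reg)
        labels.append(cond)
        if include_derivatives:
            deriv = np.diff(reg, prepend=reg[0])  # zero at the first volume
            cols.append(deriv)
            labels.append(f"{cond}_derivative")

    return DesignMatrix(np.column_stack(cols), labels, tr, dropped=dropped)


def highpass_filter(ts, sigma_s: float = 45.0, tr: float = 3.0) -> np.ndarray:
    """Gaussian-weighted running-line high-pass filter.

    At each time point a straight line is fitted by least squares with
    Gaussian weights (SD sigma_s seconds) centred there; the fitted local
    trend is subtracted and the series mean restored.  sigma_s = 45 s
    corresponds to a ~0.022 Hz cutoff.  Operates on the last axis.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    if n < 3:
        raise ValueError("series too short to filter")
    # The local weighted-line fit is linear in the data, so the whole
    # trend is one smoother matrix: trend = ts @ M with
    # M[j, i] = w_ij / sw_i + (t_i - tm_i) w_ij (t_j - tm_i) / denom_i.
    t = np.arange(n) * tr
    M = np.empty((n, n))
    for i in range(n):
        w = np.exp(-0.5 * ((t - t[i]) / sigma_s) ** 2)
        sw = w.sum()
        tm = (w * t).sum() / sw
        tc = t - tm
        denom = (w * tc**2).sum()
        M[:, i] = w / sw + (t[i] - tm) * (w * tc) / denom
    trend = ts @ M
    return ts - trend + ts.mean(axis=-1, keepdims=True)


def smooth_volume(data: np.ndarray, fwhm_mm: float = 6.0,
                  voxel_dims=(3.0, 3.0, 3.0)) -> np.ndarray:
    """Per-volume 3D Gaussian smoothing of a 3D or 4D array.

    sigma (mm) = fwhm / (2 sqrt(2 ln 2)); anisotropic voxel sizes are
    respected by converting to per-axis voxel units.  fwhm 0 is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    data = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return data.copy()
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in voxel_dims]
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox)
    if data.ndim == 4:
        out = np.empty_like(data)
        for tt in range(data.shape[3]):
            out[..., tt] = ndimage.gaussian_filter(data[..., tt], sigma=sigma_vox)
        return out
    raise ValueError("expected a 3D or 4D array")


@dataclass
class GLMFit:
    """Per-voxel OLS fit: betas (voxel x regressor), residual variance, dof."""

    betas: np.ndarray
    residual_variance: np.ndarray
    dof: int
    labels: list[str]

    def __post_init__(self) -> None:
        if self.dof <= 0:
            raise ValueError("non-positive degrees of freedom")


def fit_glm(data: np.ndarray, design: DesignMatrix, mask: np.ndarray | None = None) -> GLMFit:
    """Ordinary least squares per voxel.

    ``data`` is (x, y, z, t) or (n_voxels, t); a constant (intercept)
    column is appended internally so conditions are modelled relative to
    the implicit rest baseline.  Returns betas for the design's columns
    only (intercept discarded), residual variance RSS/dof with
    dof = n_volumes - rank(full design).
    """
    X = design.matrix
    n_vol = X.shape[0]
    Y = np.asarray(data, dtype=float)
    spatial_shape = None
    if Y.ndim == 4:
        spatial_shape = Y.shape[:3]
        Y = Y.reshape(-1, Y.shape[3])
    if Y.shape[1] != n_vol:
        raise ValueError("time dimension does not match the design")
    if mask is not None:
        Y = Y[np.asarray(mask, dtype=bool).ravel()]

    Xfull = np.column_stack([X, np.ones(n_vol)])
    rank = np.linalg.matrix_rank(Xfull)
    if rank < Xfull.shape[1]:
        raise ValueError("rank-deficient design matrix")
    dof = n_vol - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")

    pinv = np.linalg.pinv(Xfull)
    betas_full = Y @ pinv.T
    resid = Y - betas_full @ Xfull.T
    rss = (resid**2).sum(axis=1)
    fit = GLMFit(betas_full[:, :-1], rss / dof, dof, list(design.labels))
    fit.spatial_shape = spatial_shape
    return fit


@dataclass
class ContrastSpec:
    """Contrast weights over a design's main-effect regressors.

    ``weights`` maps condition name -> weight; derivative columns always
    receive 0.
    """

    weights: dict

    def __post_init__(self) -> None:
        if not self.weights or all(w == 0 for w in self.weights.values()):
            raise ValueError("contrast weights must not be all zero")

    def vector(self, labels: list[str]) -> np.ndarray:
        missing = [c for c in self.weights if c not in labels]
        if missing:
            raise ValueError(
                f"contrast names {missing} absent from design columns; "
                "check per-run condition coverage")
        return np.array([self.weights.get(l, 0.0) for l in labels])


def emotion_contrast(design: DesignMatrix, emotion: str) -> ContrastSpec:
    """Emotion-vs-patterns contrast: +1 on the emotion regressor, -1/3 on
    each pattern regressor (the mean pattern response as baseline)."""
    if emotion not in EMOTION_CONDITIONS:
        raise ValueError(f"unknown emotion condition {emotion!r}")
    needed = (emotion,) + PATTERN_CONDITIONS
    missing = [c for c in needed if c not in design.labels]
    if missing:
        raise ValueError(
            f"design is missing columns {missing} (dropped for lack of blocks); "
            "regenerate the run with full condition coverage")
    w = {p: -1.0 / 3.0 for p in PATTERN_CONDITIONS}
    w[emotion] = 1.0
    return ContrastSpec(w)


@dataclass
class CopePair:
    """Contrast of parameter estimates and its variance, per voxel."""

    cope: np.ndarray
    varcope: np.ndarray

    def __post_init__(self) -> None:
        if self.cope.shape != self.varcope.shape:
            raise ValueError("cope/varcope shape mismatch")
        if np.any(self.varcope < 0):
            raise ValueError("negative varcope")


def compute_cope(fit: GLMFit, contrast: ContrastSpec, design: DesignMatrix) -> CopePair:
    """cope = c'beta; varcope = residual_variance * c'(X'X)^-1 c.

    The quadratic form uses the same full design (including intercept)
    the fit used, with zero weight on intercept and derivatives.
    """
    c = contrast.vector(fit.labels)
    Xfull = np.column_stack([design.matrix, np.ones(design.matrix.shape[0])])
    cfull = np.append(c, 0.0)
    xtx = Xfull.T @ Xfull
    try:
        quad = float(cfull @ np.linalg.solve(xtx, cfull))
    except np.linalg.LinAlgError as e:
        raise ValueError("singular X'X; design is degenerate") from e
    cope = fit.betas @ c
    varcope = fit.residual_variance * quad
    return CopePair(cope, np.maximum(varcope, 0.0))


def fixed_effects_combine(copes: list[CopePair], weighting: str = "inverse_variance") -> CopePair:
    """Pool per-run contrast estimates within subject.

    Default inverse-variance weighting:
        cope = (sum cope_i / varcope_i) / (sum 1 / varcope_i),
        varcope = 1 / (sum 1 / varcope_i).
    Voxels where any run has zero varcope fall back to the simple average
    of copes with varcope imputed from the smallest positive varcope.
    ``weighting="average"`` gives the unweighted mean throughout.
    """
    if not copes:
        raise ValueError("no runs to combine")
    shapes = {cp.cope.shape for cp in copes}
    if len(shapes) > 1:
        raise ValueError("runs are on mismatched voxel grids")
    C = np.stack([cp.cope for cp in copes])
    V = np.stack([cp.varcope for cp in copes])

    if weighting == "average":
        return CopePair(C.mean(axis=0), V.mean(axis=0) / len(copes))
    if weighting != "inverse_variance":
        raise ValueError("weighting must be 'inverse_variance' or 'average'")

    zero = np.any(V == 0, axis=0)
    Vsafe = np.where(V == 0, 1.0, V)
    wsum = (1.0 / Vsafe).sum(axis=0)
    cope = ((C / Vsafe).sum(axis=0)) / wsum
    varcope = 1.0 / wsum
    if np.any(zero):
        pos = V[V > 0]
        fill = pos.min() if pos.size else 0.0
        cope = np.where(zero, C.mean(axis=0), cope)
        varcope = np.where(zero, fill, varcope)
    return CopePair(cope, varcope)
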