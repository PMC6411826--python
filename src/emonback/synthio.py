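"""Synthetic study generator: cohort, paradigm, behavior and BOLD volumes.

Emulates a two-group (control vs currently-depressed) emotional 3-back
study: six task conditions (happy/sad/neutral faces; vertical/horizontal/
checked patterns) in a two-run, 32-block design, DASS-21 symptom scores in
group-appropriate ranges, condition-level accuracy/RT structure, and 4D
BOLD-like runs in which a configurable voxel mask carries a
group-dependent happy-condition amplitude.  Every generator is a pure
function of (config, seed), so each downstream stage can be tested
against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .glm import EMOTION_CONDITIONS, PATTERN_CONDITIONS, TASK_CONDITIONS, HRFParams, build_design

__all__ = [
    "Block",
    "ParadigmRun",
    "Paradigm",
    "ParadigmConfig",
    "BoldRun",
    "GroundTruth",
    "BehaviorEffects",
    "gen_cohort",
    "gen_paradigm",
    "gen_behavior",
    "gen_bold",
    "default_ground_truth",
]

DASS_SCALES = ("dass_depression", "dass_anxiety", "dass_stress")

# Group-level score-generating parameters: mean, SD, and admissible range
# per DASS-21 subscale (0-42 doubled-score convention).  Control depression
# is capped below the screening cut-off; depressed depression starts at the
# "moderate" rating.
_DASS_DEFAULTS = {
    "control": {
        "dass_depression": (1.43, 1.45, (0, 11)),
        "dass_anxiety": (1.43, 1.22, (0, 42)),
        "dass_stress": (5.71, 4.95, (0, 42)),
    },
    "depressed": {
        "dass_depression": (28.62, 6.99, (14, 42)),
        "dass_anxiety": (21.38, 10.60, (0, 42)),
        "dass_stress": (27.08, 9.54, (0, 42)),
    },
}

_AGE_DEFAULTS = {"control": (29.79, 9.62), "depressed": (30.62, 9.99)}
_MALE_P = {"control": 6 / 14, "depressed": 3 / 13}
_MEDICATED_P = 9 / 13


def gen_cohort(n_control: int, n_depressed: int, score_ranges: dict | None = None,
               seed: int = 0) -> pd.DataFrame:
    """Generate a participant table for the two groups.

    DASS-21 subscale scores are integer draws from a clipped normal whose
    mean/SD follow the study-typical group profiles; ``score_ranges`` may
    override the admissible (low, high) range per group and scale.  Ages
    are clipped to the 18-65 recruitment window.
    """
    if n_control < 1 or n_depressed < 1:
        raise ValueError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, prefix in [("control", n_control, "C"), ("depressed", n_depressed, "D")]:
        for i in range(n):
            row = {"subject_id": f"sub-{prefix}{i + 1:02d}", "group": group}
            age = rng.normal(*_AGE_DEFAULTS[group])
            row["age"] = float(np.clip(age, 18.0, 65.0))
            row["sex"] = "M" if rng.random() < _MALE_P[group] else "F"
            for scale in DASS_SCALES:
                mean, sd, default_range = _DASS_DEFAULTS[group][scale]
                lo, hi = default_range
                if score_ranges and scale in score_ranges.get(group, {}):
                    lo, hi = score_ranges[group][scale]
                if lo > hi:
                    raise ValueError(f"inverted range for {group}/{scale}: ({lo}, {hi})")
                score = int(round(np.clip(rng.normal(mean, sd), lo, hi)))
                row[scale] = score
            row["medicated"] = bool(rng.random() < _MEDICATED_P) if group == "depressed" else False
            row["included"] = True
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paradigm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    onset: float
    duration: float
    condition: str


@dataclass
class ParadigmRun:
    blocks: list[Block]
    n_volumes: int
    tr: float


@dataclass
class Paradigm:
    runs: list[ParadigmRun]
    tr: float
    trials_per_block: int
    trial_fixation_s: float
    trial_stimulus_s: float

    def events_frame(self, run_index: int) -> pd.DataFrame:
        """Events-file view of one run (onset, duration, trial_type)."""
        blocks = self.runs[run_index].blocks
        return pd.DataFrame({
            "onset": [b.onset for b in blocks],
            "duration": [b.duration for b in blocks],
            "trial_type": [b.condition for b in blocks],
        })


@dataclass
class ParadigmConfig:
    """Block-design layout: 32 blocks over two runs by default, 16.2 s
    blocks of 9 trials (2 s fixation + 1.6 s stimulus each), faces and
    patterns alternating, happy and horizontal appearing six times and
    the other conditions five.  Inter-block rest is sized so the blocks
    and rests exactly fill n_volumes x tr per run."""

    n_runs: int = 2
    blocks_per_run: int = 16
    block_duration_s: float = 16.2
    tr: float = 3.0
    n_volumes: int = 168
    trials_per_block: int = 9
    trial_fixation_s: float = 2.0
    trial_stimulus_s: float = 1.6
    condition_counts: dict = field(default_factory=lambda: {
        "happy": 6, "sad": 5, "neutral": 5,
        "horizontal": 6, "vertical": 5, "checked": 5,
    })

    @property
    def rest_s(self) -> float:
        run_s = self.n_volumes * self.tr
        return (run_s - self.blocks_per_run * self.block_duration_s) / self.blocks_per_run


def _split_counts(counts: dict, n_runs: int, per_run_total: int,
                  rng: np.random.Generator, max_tries: int = 2000) -> list[dict]:
    """Split per-condition totals into per-run counts (each within one of
    floor/ceil of the even split) so each run receives per_run_total."""
    conds = list(counts)
    for _ in range(max_tries):
        per_run = [dict.fromkeys(conds, 0) for _ in range(n_runs)]
        ok = True
        for c in conds:
            base, extra = divmod(counts[c], n_runs)
            alloc = [base] * n_runs
            for j in rng.choice(n_runs, size=extra, replace=False):
                alloc[j] += 1
            for r in range(n_runs):
                per_run[r][c] = alloc[r]
        for r in range(n_runs):
            if sum(per_run[r].values()) != per_run_total:
                ok = False
                break
        if ok:
            return per_run
    raise ValueError("could not split condition counts evenly across runs")


def gen_paradigm(config: ParadigmConfig | None = None, seed: int = 0) -> Paradigm:
    """Generate the alternating faces/patterns block paradigm.

    Within each run, face and pattern blocks strictly alternate (start
    type randomised by seed); the per-run allocation of each condition
    keeps all totals at their configured counts.
    """
    config = config or ParadigmConfig()
    face_total = sum(config.condition_counts.get(c, 0) for c in EMOTION_CONDITIONS)
    pattern_total = sum(config.condition_counts.get(c, 0) for c in PATTERN_CONDITIONS)
    total = config.n_runs * config.blocks_per_run
    if face_total + pattern_total != total:
        raise ValueError(
            f"condition counts sum to {face_total + pattern_total}, expected {total}")
    if face_total != pattern_total:
        raise ValueError("faces and patterns must have equal totals for alternation")
    if config.blocks_per_run % 2 != 0:
        raise ValueError("blocks_per_run must be even to alternate")
    if config.rest_s < 0:
        raise ValueError("blocks do not fit in the run: negative rest duration")

    rng = np.random.default_rng(seed)
    half = config.blocks_per_run // 2
    face_runs = _split_counts(
        {c: config.condition_counts.get(c, 0) for c in EMOTION_CONDITIONS},
        config.n_runs, half, rng)
    pattern_runs = _split_counts(
        {c: config.condition_counts.get(c, 0) for c in PATTERN_CONDITIONS},
        config.n_runs, half, rng)

    runs = []
    for r in range(config.n_runs):
        faces = [c for c in EMOTION_CONDITIONS for _ in range(face_runs[r][c])]
        patterns = [c for c in PATTERN_CONDITIONS for _ in range(pattern_runs[r][c])]
        rng.shuffle(faces)
        rng.shuffle(patterns)
        first, second = (faces, patterns) if rng.random() < 0.5 else (patterns, faces)
        order = [x for pair in zip(first, second) for x in pair]
        blocks = []
        step = config.block_duration_s + config.rest_s
        for i, cond in enumerate(order):
            onset = config.rest_s + i * step
            blocks.append(Block(onset=onset, duration=config.block_duration_s, condition=cond))
        runs.append(ParadigmRun(blocks=blocks, n_volumes=config.n_volumes, tr=config.tr))
    return Paradigm(runs=runs, tr=config.tr,
                    trials_per_block=config.trials_per_block,
                    trial_fixation_s=config.trial_fixation_s,
                    trial_stimulus_s=config.trial_stimulus_s)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

# Generating means per group and condition (accuracy proportion, RT ms),
# matching the magnitude of a typical emotional n-back: ~0.7-0.8 accuracy,
# slower responses to faces than patterns.
_ACC_MEANS = {
    "control": {"happy": 0.71, "sad": 0.74, "neutral": 0.79,
                "vertical": 0.78, "horizontal": 0.75, "checked": 0.80},
    "depressed": {"happy": 0.70, "sad": 0.73, "neutral": 0.74,
                  "vertical": 0.75, "horizontal": 0.77, "checked": 0.79},
}
_RT_MEANS = {
    "control": {"happy": 794.15, "sad": 778.21, "neutral": 763.62,
                "vertical": 684.47, "horizontal": 667.86, "checked": 680.33},
    "depressed": {"happy": 820.60, "sad": 811.87, "neutral": 807.26,
                  "vertical": 736.87, "horizontal": 672.34, "checked": 718.47},
}


@dataclass
class BehaviorEffects:
    """Generative model for behavior: per-group condition means plus a
    subject-level random intercept plus i.i.d. Gaussian noise.

    The SDs split the observed ~0.15 (accuracy) / ~110 ms (RT) per-cell
    spread into a between-subject and a residual component."""

    acc_means: dict = field(default_factory=lambda: {g: dict(v) for g, v in _ACC_MEANS.items()})
    rt_means: dict = field(default_factory=lambda: {g: dict(v) for g, v in _RT_MEANS.items()})
    subject_sd_acc: float = 0.12
    resid_sd_acc: float = 0.08
    subject_sd_rt: float = 90.0
    resid_sd_rt: float = 55.0


def gen_behavior(cohort: pd.DataFrame, effects: BehaviorEffects | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """One accuracy/RT row per subject x condition.

    Accuracy is clipped to [0, 1] and RT floored at 1 ms.  With all SDs
    zero every value equals its group/condition generating mean.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    effects = effects or BehaviorEffects()
    rng = np.random.default_rng(seed)
    rows = []
    for _, subj in cohort.iterrows():
        g = subj["group"]
        int_acc = rng.normal(0.0, effects.subject_sd_acc) if effects.subject_sd_acc else 0.0
        int_rt = rng.normal(0.0, effects.subject_sd_rt) if effects.subject_sd_rt else 0.0
        for cond in TASK_CONDITIONS:
            acc = effects.acc_means[g][cond] + int_acc
            rt = effects.rt_means[g][cond] + int_rt
            if effects.resid_sd_acc:
                acc += rng.normal(0.0, effects.resid_sd_acc)
            if effects.resid_sd_rt:
                rt += rng.normal(0.0, effects.resid_sd_rt)
            rows.append({
                "subject_id": subj["subject_id"],
                "group": g,
                "condition": cond,
                "accuracy": float(np.clip(acc, 0.0, 1.0)),
                "rt": float(max(rt, 1.0)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------

@dataclass
class BoldRun:
    """4D voxel array with acquisition geometry."""

    data: np.ndarray
    tr: float
    voxel_dims: tuple = (3.0, 3.0, 3.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.mask is not None and self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial dimensions")


@dataclass
class GroundTruth:
    """The simulator's truth record.

    baseline_betas are condition amplitudes applied at every brain voxel;
    condition_betas[group][condition] is the extra amplitude added inside
    effect_mask for that group's subjects.  Noise is AR(1) Gaussian with
    stationary SD noise_sd plus a per-voxel linear drift whose amplitude
    scales with noise_sd (a noiseless simulation is therefore exactly the
    convolved design prediction plus baseline_offset)."""

    effect_mask: np.ndarray | None = None
    condition_betas: dict = field(default_factory=lambda: {
        "control": {"happy": 1.0},
        "depressed": {"happy": 0.0},
    })
    baseline_betas: dict = field(default_factory=lambda: dict.fromkeys(TASK_CONDITIONS, 0.5))
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_rel_amplitude: float = 0.5
    baseline_offset: float = 100.0
    # optional per-subject multiplier on the effect-mask amplitudes, e.g.
    # to tie a subject's activation monotonically to a clinical score
    subject_effect_scale: dict | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1.0 < self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must be in (-1, 1)")


def _default_brain_mask(shape: tuple) -> np.ndarray:
    """Ellipsoid filling the volume with a one-voxel margin."""
    grids = np.indices(shape).astype(float)
    centre = [(s - 1) / 2.0 for s in shape]
    semi = [max((s - 3) / 2.0, 1.0) for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


def default_ground_truth(shape: tuple, **overrides) -> GroundTruth:
    """GroundTruth with a cubic effect region placed off-centre inside the
    default brain mask (side ~ shape/4, minimum 3 voxels)."""
    mask = _default_brain_mask(shape)
    side = max(3, min(shape) // 4)
    start = [max(1, s // 2 - side) for s in shape]
    effect = np.zeros(shape, dtype=bool)
    sl = tuple(slice(st, st + side) for st in start)
    effect[sl] = True
    effect &= mask
    return GroundTruth(effect_mask=effect, **overrides)


def _ar1_noise(rng: np.random.Generator, shape: tuple, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with marginal SD sd."""
    w = rng.standard_normal(shape) * sd * math.sqrt(max(1.0 - phi**2, 1e-12))
    e = lfilter([1.0], [1.0, -phi], w, axis=-1)
    return e


def gen_bold(cohort: pd.DataFrame, paradigm: Paradigm,
             truth: GroundTruth | None = None, shape: tuple = (16, 16, 16),
             seed: int = 0, voxel_dims: tuple = (3.0, 3.0, 3.0)) -> tuple[dict, GroundTruth]:
    """Forward-simulate one BOLD run per paradigm run for every subject.

    Signal: condition boxcars convolved with the canonical double-gamma
    HRF, scaled by baseline_betas everywhere in the brain mask, plus the
    per-group condition_betas inside effect_mask, plus baseline_offset.
    Noise: AR(1) Gaussian (stationary SD noise_sd) and a linear drift of
    amplitude drift_rel_amplitude x noise_sd over the run, both only when
    noise_sd > 0.  Outside the brain mask the data are exactly zero.

    Returns ({subject_id: [BoldRun per run]}, truth-with-mask-filled).
    """
    if any(s < 8 for s in shape):
        raise ValueError("shape must be at least 8 voxels per axis")
    truth = truth or default_ground_truth(shape)
    if truth.effect_mask is None:
        truth = replace(truth, effect_mask=default_ground_truth(shape).effect_mask)
    if truth.effect_mask.shape != shape:
        raise ValueError("effect_mask shape does not match requested volume shape")
    brain = _default_brain_mask(shape)
    if not truth.effect_mask.any():
        raise ValueError("effect_mask is empty for this shape")
    if np.any(truth.effect_mask & ~brain):
        raise ValueError("effect_mask extends outside the brain mask")

    rng = np.random.default_rng(seed)
    n_brain = int(brain.sum())
    effect_in_brain = truth.effect_mask[brain]

    # Per-run condition regressors sampled at volume times (no derivatives:
    # the forward model is the main-effect prediction).
    designs = []
    for r, run in enumerate(paradigm.runs):
        designs.append(build_design(paradigm, r, run.n_volumes, run.tr,
                                    HRFParams(), include_derivatives=False))

    out: dict[str, list[BoldRun]] = {}
    for _, subj in cohort.iterrows():
        g = subj["group"]
        scale = 1.0
        if truth.subject_effect_scale is not None:
            scale = float(truth.subject_effect_scale.get(subj["subject_id"], 1.0))
        extra = {c: a * scale for c, a in truth.condition_betas.get(g, {}).items()}
        runs_out = []
        for r, run in enumerate(paradigm.runs):
            X = designs[r].matrix
            labels = designs[r].labels
            n_vol = run.n_volumes
            betas = np.zeros((n_brain, len(labels)))
            for j, cond in enumerate(labels):
                betas[:, j] = truth.baseline_betas.get(cond, 0.0)
                if cond in extra:
                    betas[effect_in_brain, j] += extra[cond]
            sig = betas @ X.T + truth.baseline_offset
            if truth.noise_sd > 0:
                sig = sig + _ar1_noise(rng, (n_brain, n_vol), truth.noise_sd, truth.ar1_coef)
                slope = rng.uniform(-1.0, 1.0, size=n_brain)
                drift = truth.drift_rel_amplitude * truth.noise_sd
                ramp = np.linspace(-0.5, 0.5, n_vol)
                sig = sig + drift * slope[:, None] * ramp[None, :]
            vol = np.zeros(shape + (n_vol,))
            vol[brain] = sig
            runs_out.append(BoldRun(data=vol, tr=run.tr, voxel_dims=voxel_dims, mask=brain))
        out[subj["subject_id"]] = runs_out
    return out, truth
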