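"""End-to-end orchestration: simulate -> screen -> behavioral stats ->
first-level GLM -> group inference -> cluster extraction -> clinical
correlations, with file I/O, a JSON manifest and a command-line surface.

One global seed deterministically derives every stage seed (SHA-256 of
"<seed>:<stage>", truncated below 2^31), so a run is reproducible from its
config alone and any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import clinassoc, glm, inference, permcore, screening, synthio

logger = logging.getLogger("emonback")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "first_level_copes",
    "read_nifti",
    "write_nifti",
    "derive_seed",
    "cli",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: SHA-256 of "<seed>:<stage>" mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_nifti(data: np.ndarray, path, voxel_dims=(3.0, 3.0, 3.0)) -> None:
    """Write an array as NIfTI-1 (gzip or plain by extension) with a
    diagonal affine from the voxel dimensions."""
    affine = np.diag(list(voxel_dims) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_nifti(path, squeeze: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI-1 file; returns (data, affine).

    A 4D image with a singleton time dimension is squeezed to 3D when
    ``squeeze`` (the documented dialect for statistic maps saved by tools
    that always emit 4D).
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if squeeze and data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return data, img.affine


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Study-replica configuration.

    Defaults are a desk-scale replica: the full two-run 32-block paradigm
    and two groups of 14 and 13 subjects, but a 12^3 voxel grid and
    R = 200 reshuffles so the whole pipeline completes in minutes on one
    CPU.  Raise ``shape``/``n_reshuffles`` for higher-fidelity runs.
    """

    out_dir: str = "emonback_out"
    seed: int = 0
    n_control: int = 14
    n_depressed: int = 13
    # scaled-down whole-brain grid: coarse voxels keep the field of view
    # brain-sized (12^3 x 16 mm ~ 190 mm), so mm-specified preprocessing
    # (6 mm smoothing) stays physically meaningful
    shape: tuple = (12, 12, 12)
    voxel_dims: tuple = (16.0, 16.0, 16.0)
    n_reshuffles: int = 200
    alpha: float = 0.05
    smooth_fwhm_mm: float = 6.0
    highpass_sigma_s: float = 45.0
    paradigm: synthio.ParadigmConfig = field(default_factory=synthio.ParadigmConfig)
    screening: screening.ScreeningConfig = field(default_factory=screening.ScreeningConfig)
    hrf: glm.HRFParams = field(default_factory=glm.HRFParams)
    tfce: inference.TFCEParams = field(default_factory=inference.TFCEParams)
    truth: synthio.GroundTruth | None = None
    write_volumes: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "paradigm" in kwargs:
            kwargs["paradigm"] = synthio.ParadigmConfig(**kwargs["paradigm"])
        if "screening" in kwargs:
            kwargs["screening"] = screening.ScreeningConfig(**kwargs["screening"])
        if "hrf" in kwargs:
            kwargs["hrf"] = glm.HRFParams(**kwargs["hrf"])
        if "tfce" in kwargs:
            kwargs["tfce"] = inference.TFCEParams(**kwargs["tfce"])
        if "shape" in kwargs:
            kwargs["shape"] = tuple(kwargs["shape"])
        if "voxel_dims" in kwargs:
            kwargs["voxel_dims"] = tuple(kwargs["voxel_dims"])
        return cls(**kwargs)


def _perm_config(config: PipelineConfig, stage: str) -> permcore.PermConfig:
    return permcore.PermConfig(n_reshuffles=config.n_reshuffles,
                               seed=derive_seed(config.seed, stage),
                               alpha=config.alpha)


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# first level
# ---------------------------------------------------------------------------

def first_level_copes(bold: dict, paradigm: synthio.Paradigm,
                      config: PipelineConfig) -> tuple[dict, list, np.ndarray]:
    """Per-subject emotion-vs-patterns contrast maps, runs combined.

    For every subject and run: optional spatial smoothing, Gaussian
    running-line high-pass, OLS fit of the convolved design (with
    temporal derivatives), one cope per emotion condition; the two runs
    are pooled by inverse-variance fixed effects.

    Returns ({emotion: (n_subjects, x, y, z) cope stack}, subject order,
    brain mask).
    """
    subjects = list(bold)
    mask = bold[subjects[0]][0].mask
    flat_mask = mask.ravel()
    designs = []
    for r, run in enumerate(paradigm.runs):
        d = glm.build_design(paradigm, r, run.n_volumes, run.tr,
                             config.hrf, include_derivatives=True)
        if config.highpass_sigma_s > 0:
            # filter design and data with the same operator so the fit is
            # unbiased for the frequencies the filter keeps
            d = glm.DesignMatrix(
                glm.highpass_filter(d.matrix.T, config.highpass_sigma_s, run.tr).T
                - d.matrix.mean(axis=0),
                d.labels, d.tr, dropped=d.dropped)
        designs.append(d)

    stacks = {emo: np.zeros((len(subjects),) + mask.shape)
              for emo in glm.EMOTION_CONDITIONS}
    for si, subj in enumerate(subjects):
        per_run: dict[str, list[glm.CopePair]] = {emo: [] for emo in glm.EMOTION_CONDITIONS}
        for r, run in enumerate(bold[subj]):
            data = run.data
            if config.smooth_fwhm_mm > 0:
                data = glm.smooth_volume(data, config.smooth_fwhm_mm, run.voxel_dims)
            Y = data.reshape(-1, data.shape[3])[flat_mask]
            if config.highpass_sigma_s > 0:
                Y = glm.highpass_filter(Y, config.highpass_sigma_s, run.tr)
            fit = glm.fit_glm(Y, designs[r])
            for emo in glm.EMOTION_CONDITIONS:
                spec = glm.emotion_contrast(designs[r], emo)
                per_run[emo].append(glm.compute_cope(fit, spec, designs[r]))
        for emo in glm.EMOTION_CONDITIONS:
            combined = glm.fixed_effects_combine(per_run[emo])
            vol = np.zeros(mask.shape)
            vol[mask] = combined.cope
            stacks[emo][si] = vol
    return stacks, subjects, mask


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study replica; returns the manifest dict.

    The manifest records, per stage, the derived seed, wall time, output
    files and content hashes of the deterministic arrays, and is written
    to ``<out_dir>/manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_seed": config.seed, "stages": {}}
    t_start = time.time()

    def stage_done(name: str, seed: int, info: dict) -> None:
        info = dict(info)
        info["seed"] = seed
        info["elapsed_s"] = round(time.time() - stage_t0, 2)
        manifest["stages"][name] = info
        logger.info("stage %s done in %.1fs", name, info["elapsed_s"])

    # -- simulate -----------------------------------------------------------
    stage_t0 = time.time()
    seed_sim = derive_seed(config.seed, "simulate")
    cohort = synthio.gen_cohort(config.n_control, config.n_depressed, seed=seed_sim)
    paradigm = synthio.gen_paradigm(config.paradigm, seed=derive_seed(config.seed, "paradigm"))
    behavior = synthio.gen_behavior(cohort, seed=derive_seed(config.seed, "behavior"))
    truth = config.truth or synthio.default_ground_truth(tuple(config.shape))
    bold, truth = synthio.gen_bold(cohort, paradigm, truth, tuple(config.shape),
                                   seed=derive_seed(config.seed, "bold"),
                                   voxel_dims=tuple(config.voxel_dims))
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    for r in range(len(paradigm.runs)):
        paradigm.events_frame(r).to_csv(out / f"events_run-{r + 1}.tsv", sep="\t", index=False)
    write_nifti(truth.effect_mask.astype(float), out / "effect_mask.nii.gz", config.voxel_dims)
    if config.write_volumes:
        for subj, runs in bold.items():
            for r, run in enumerate(runs):
                write_nifti(run.data, out / f"{subj}_run-{r + 1}_bold.nii.gz", run.voxel_dims)
    stage_done("simulate", seed_sim, {
        "n_subjects": len(cohort),
        "cohort_hash": _hash_array(cohort["dass_depression"].to_numpy()),
        "outputs": ["cohort.tsv", "behavior.tsv", "effect_mask.nii.gz"],
    })

    # -- screen -------------------------------------------------------------
    stage_t0 = time.time()
    seed_screen = derive_seed(config.seed, "screen")
    included, excluded = screening.apply_screening(cohort, config.screening)
    report = screening.screening_report(included, excluded, config.screening)
    sex = pd.crosstab(included["group"], included["sex"])
    a = int(sex.loc["control"].get("M", 0))
    b = int(sex.loc["control"].get("F", 0))
    c = int(sex.loc["depressed"].get("M", 0))
    d = int(sex.loc["depressed"].get("F", 0))
    odds, p_sex = screening.fisher_exact_2x2(a, b, c, d)
    ctrl = included[included["group"] == "control"]
    dep = included[included["group"] == "depressed"]
    demo = {}
    for col in ("age",) + synthio.DASS_SCALES:
        res = screening.compare_groups_continuous(
            ctrl[col], dep[col], _perm_config(config, f"screen:{col}"))
        demo[col] = res.to_dict()
    report["sex_fisher"] = {"odds_ratio": odds, "p": p_sex}
    report["group_comparisons"] = demo
    (out / "screening.json").write_text(json.dumps(report, indent=2))
    stage_done("screen", seed_screen, {
        "n_included": len(included), "n_excluded": len(excluded),
        "outputs": ["screening.json"],
    })
    cohort = included  # downstream stages see the screened cohort

    # -- behavioral stats ---------------------------------------------------
    stage_t0 = time.time()
    seed_behave = derive_seed(config.seed, "behave")
    emotions = behavior[behavior["condition"].isin(glm.EMOTION_CONDITIONS)]
    emotions = emotions[emotions["subject_id"].isin(cohort["subject_id"])]
    behave_results = {}
    for measure in ("accuracy", "rt"):
        anova = permcore.perm_mixed_anova(
            emotions, _perm_config(config, f"behave:{measure}"),
            subject="subject_id", group="group", condition="condition", value=measure)
        behave_results[measure] = {k: v.to_dict() for k, v in anova.items()}
    # post-hoc pairwise sign-flip tests across all six conditions, maxT-corrected
    wide = behavior[behavior["subject_id"].isin(cohort["subject_id"])]
    posthoc = {}
    for measure in ("accuracy", "rt"):
        pivot = wide.pivot(index="subject_id", columns="condition", values=measure)
        members = []
        names = []
        cfg = _perm_config(config, f"posthoc:{measure}")
        for c1, c2 in itertools.combinations(glm.TASK_CONDITIONS, 2):
            members.append(permcore.perm_signed_rank(pivot[c1], pivot[c2], cfg))
            names.append(f"{c1}-{c2}")
        fam = permcore.maxt_adjust(members)
        posthoc[measure] = {n: m.to_dict() for n, m in zip(names, fam.members)}
    (out / "behavior_stats.json").write_text(json.dumps(
        {"mixed_anova": behave_results, "posthoc": posthoc}, indent=2))
    stage_done("behave", seed_behave, {"outputs": ["behavior_stats.json"]})

    # -- first-level GLM ----------------------------------------------------
    stage_t0 = time.time()
    seed_glm = derive_seed(config.seed, "glm")
    bold = {s: runs for s, runs in bold.items() if s in set(cohort["subject_id"])}
    stacks, subjects, mask = first_level_copes(bold, paradigm, config)
    if config.write_volumes:
        for emo, stack in stacks.items():
            for si, subj in enumerate(subjects):
                write_nifti(stack[si], out / f"{subj}_cope-{emo}.nii.gz", config.voxel_dims)
    stage_done("glm", seed_glm, {
        "n_subjects": len(subjects),
        "cope_hashes": {emo: _hash_array(stack) for emo, stack in stacks.items()},
    })

    # -- group inference ----------------------------------------------------
    stage_t0 = time.time()
    seed_infer = derive_seed(config.seed, "infer")
    group_of = dict(zip(cohort["subject_id"], cohort["group"]))
    is_control = np.array([group_of[s] == "control" for s in subjects])
    infer_summary = {}
    cluster_tables = {}
    label_vols = {}
    for emo, stack in stacks.items():
        t1, tf1, fwe1, _ = inference.perm_one_sample(
            stack, mask, _perm_config(config, f"infer:one:{emo}"), config.tfce)
        t2, tf2, fwe2, _ = inference.perm_two_sample(
            stack[is_control], stack[~is_control], mask,
            _perm_config(config, f"infer:two:{emo}"), config.tfce)
        table, labels = inference.significant_clusters(
            fwe2, t2, config.alpha, config.tfce.connectivity, tuple(config.voxel_dims))
        cluster_tables[emo] = table
        label_vols[emo] = labels
        table.to_csv(out / f"clusters_{emo}.tsv", sep="\t", index=False)
        write_nifti(t2, out / f"tmap_two-sample_{emo}.nii.gz", config.voxel_dims)
        write_nifti(fwe2, out / f"fwep_two-sample_{emo}.nii.gz", config.voxel_dims)
        infer_summary[emo] = {
            "one_sample_sig_voxels": int(np.sum(fwe1[mask] <= config.alpha)),
            "two_sample_sig_voxels": int(np.sum(fwe2[mask] <= config.alpha)),
            "n_clusters": int(len(table)),
            "tmap_hash": _hash_array(t2),
        }
    stage_done("infer", seed_infer, {"contrasts": infer_summary})

    # -- clinical correlations ---------------------------------------------
    stage_t0 = time.time()
    seed_corr = derive_seed(config.seed, "correlate")
    corr_out: dict = {}
    for emo, table in cluster_tables.items():
        if not len(table):
            continue
        means = inference.extract_cluster_means(
            label_vols[emo], table["label"].tolist(), stacks[emo])
        cm = pd.DataFrame(means, columns=[f"cluster_{lab}" for lab in table["label"]])
        cm.insert(0, "subject_id", subjects)
        cm.to_csv(out / f"cluster_means_{emo}.tsv", sep="\t", index=False)
        emo_res = {}
        for grp in ("control", "depressed"):
            fam = clinassoc.correlate_clusters_clinical(
                cm, cohort, grp, _perm_config(config, f"corr:{emo}:{grp}"))
            emo_res[grp] = {m.statistic_name: m.to_dict() for m in fam.members}
        delta = clinassoc.compare_group_correlations(
            cm, cohort, "depressed", "control", _perm_config(config, f"corr:{emo}:delta"))
        emo_res["delta_rho"] = {k: v.to_dict() for k, v in delta.items()}
        corr_out[emo] = emo_res
    (out / "clinical_correlations.json").write_text(json.dumps(corr_out, indent=2))
    stage_done("correlate", seed_corr, {"contrasts_with_clusters": list(corr_out)})

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# ground-truth recovery study
# ---------------------------------------------------------------------------

def recovery_study(seed: int, shape: tuple = (16, 16, 16), n_control: int = 14,
                   n_depressed: int = 13, n_reshuffles: int = 500,
                   alpha: float = 0.05) -> dict:
    """One full replica with known ground truth; report what was recovered.

    Only the control group carries extra happy-condition amplitude in the
    effect mask; depressed subjects carry a smaller amplitude scaled
    monotonically by their DASS-21 depression score (the injected
    brain-behavior link).  Runs the two-sample contrast for every emotion
    and the clinical-correlation stage on the happy clusters.

    Returns per-emotion FWE-significant voxel counts, the happy-contrast
    Dice overlap with the effect mask, and whether any happy cluster's
    correlation with the depression scale survived maxT in the depressed
    group.
    """
    shape = tuple(shape)
    voxel_dims = tuple(190.0 / s for s in shape)  # brain-sized FOV
    cfg = PipelineConfig(shape=shape, voxel_dims=voxel_dims,
                         n_reshuffles=n_reshuffles, alpha=alpha, seed=seed)
    cohort = synthio.gen_cohort(n_control, n_depressed, seed=derive_seed(seed, "cohort"))
    paradigm = synthio.gen_paradigm(cfg.paradigm, seed=derive_seed(seed, "paradigm"))

    dep = cohort[cohort["group"] == "depressed"]
    scores = dep["dass_depression"].to_numpy(dtype=float)
    span = scores.max() - scores.min()
    u = (scores - scores.min()) / span if span > 0 else np.full(len(scores), 0.5)
    truth = synthio.default_ground_truth(
        shape,
        condition_betas={"control": {"happy": 1.0}, "depressed": {"happy": 0.6}},
        subject_effect_scale=dict(zip(dep["subject_id"], u)),
    )
    bold, truth = synthio.gen_bold(cohort, paradigm, truth, shape,
                                   seed=derive_seed(seed, "bold"), voxel_dims=voxel_dims)
    stacks, subjects, mask = first_level_copes(bold, paradigm, cfg)
    group_of = dict(zip(cohort["subject_id"], cohort["group"]))
    is_control = np.array([group_of[s] == "control" for s in subjects])

    out: dict = {"seed": seed, "sig_voxels": {}, "dice": {}}
    happy_table = happy_labels = None
    for emo in glm.EMOTION_CONDITIONS:
        t2, _, fwe2, _ = inference.perm_two_sample(
            stacks[emo][is_control], stacks[emo][~is_control], mask,
            _perm_config(cfg, f"infer:two:{emo}"), cfg.tfce)
        sig = fwe2 <= alpha
        out["sig_voxels"][emo] = int(sig.sum())
        out["dice"][emo] = inference.dice(sig, truth.effect_mask)
        if emo == "happy":
            happy_table, happy_labels = inference.significant_clusters(
                fwe2, t2, alpha, cfg.tfce.connectivity, voxel_dims)

    out["link_detected"] = False
    out["n_happy_clusters"] = int(len(happy_table)) if happy_table is not None else 0
    if happy_table is not None and len(happy_table):
        means = inference.extract_cluster_means(
            happy_labels, happy_table["label"].tolist(), stacks["happy"])
        cm = pd.DataFrame(means, columns=[f"cluster_{lab}" for lab in happy_table["label"]])
        cm.insert(0, "subject_id", subjects)
        fam = clinassoc.correlate_clusters_clinical(
            cm, cohort, "depressed", _perm_config(cfg, "corr:happy:depressed"))
        best = None
        for m in fam.members:
            if m.statistic_name.endswith("~dass_depression)"):
                if best is None or m.p_adjusted < best:
                    best = m.p_adjusted
        out["link_best_p_adjusted"] = best
        out["link_detected"] = best is not None and best <= alpha
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Emotional 3-back permutation pipeline on synthetic data."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def _load_config(config_path, out_dir, seed):
    cfg = PipelineConfig.from_file(config_path) if config_path else PipelineConfig()
    if out_dir:
        cfg.out_dir = out_dir
    if seed is not None:
        cfg.seed = seed
    return cfg


@cli.command("all")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out-dir", default=None)
@click.option("--seed", type=int, default=None)
def cli_all(config_path, out_dir, seed) -> None:
    """Run every stage end to end."""
    manifest = run_pipeline(_load_config(config_path, out_dir, seed))
    click.echo(json.dumps({"stages": list(manifest["stages"]),
                           "elapsed_s": manifest["elapsed_s"]}, indent=2))


@cli.command("simulate")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out-dir", default=None)
@click.option("--seed", type=int, default=None)
def cli_simulate(config_path, out_dir, seed) -> None:
    """Generate cohort, paradigm events, behavior and BOLD volumes only."""
    cfg = _load_config(config_path, out_dir, seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = synthio.gen_cohort(cfg.n_control, cfg.n_depressed,
                                seed=derive_seed(cfg.seed, "simulate"))
    paradigm = synthio.gen_paradigm(cfg.paradigm, seed=derive_seed(cfg.seed, "paradigm"))
    behavior = synthio.gen_behavior(cohort, seed=derive_seed(cfg.seed, "behavior"))
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    for r in range(len(paradigm.runs)):
        paradigm.events_frame(r).to_csv(out / f"events_run-{r + 1}.tsv", sep="\t", index=False)
    click.echo(f"wrote cohort ({len(cohort)} subjects) and events to {out}")


@cli.command("screen")
@click.option("--cohort", "cohort_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", default="screening.json")
def cli_screen(cohort_path, out_path) -> None:
    """Apply DASS-21 inclusion rules to a cohort TSV."""
    cohort = pd.read_csv(cohort_path, sep="\t")
    cfg = screening.ScreeningConfig()
    included, excluded = screening.apply_screening(cohort, cfg)
    report = screening.screening_report(included, excluded, cfg)
    Path(out_path).write_text(json.dumps(report, indent=2))
    click.echo(f"{len(included)} included, {len(excluded)} excluded -> {out_path}")
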