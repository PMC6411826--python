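# Methods

## Permutation framework

All hypothesis tests are permutation tests. For a statistic T and a
reshuffling scheme appropriate to its null hypothesis, the two-sided
Monte-Carlo p-value is

    p = (1 + #{r : |T_r| >= |T_obs|}) / (R + 1),

which counts the observed arrangement as one draw from the null and is
therefore valid (never zero, never anti-conservative in expectation).
When the arrangement space is small — at most 20,000 group assignments,
sign patterns or pairings — the tests enumerate it exhaustively and
report the exact p = #{|T_pi| >= |T_obs|} / #arrangements instead. The
default Monte-Carlo depth is R = 10,000 reshuffles; the bundled
test-suite and replica configurations use R = 200–2,000 so that a full
run stays in minutes on one CPU (a choice of problem size, not of
method).

Schemes per test:

- **Two-sample t** (age, DASS scores, demographics): pooled-variance t;
  group labels reassigned with sizes preserved.
- **Mixed-design ANOVA** (condition x group on accuracy and RT):
  classical F values from the standard sums-of-squares decomposition
  with subjects-within-group as the between-effect error stratum and the
  condition x subject residual for within/interaction. The reshuffling
  is Manly-style raw-label permutation per stratum: group labels across
  subjects for the between effect; condition labels independently within
  each subject for the within and interaction effects. This scheme is
  exact under the global null; residual-based schemes (better under some
  partial nulls) are a documented alternative, not implemented.
- **Paired post-hocs**: differences d = x − y (zeros dropped), null by
  independent sign flips. The reported statistic is the paired t on d —
  the scale such comparisons are conventionally printed on — with the
  centred signed-rank sum available via `statistic="wilcoxon"`; both
  share the same distribution-free null.
- **Spearman ρ**: Pearson correlation of midranks; y permuted against
  fixed x.
- **Δρ** (between-group correlation difference): (x, y) pairs reassigned
  to groups, ranks recomputed within each permuted group. A permuted
  group that becomes constant contributes Δρ = 0 for that reshuffle and
  is counted in the result (`n_degenerate`).

**maxT correction.** A family of tests evaluated under one synchronized
permutation stream (same scheme, R and seed, so reshuffle r means the
same relabelling for every member) is corrected single-step: the null is
the per-reshuffle maximum of |T| over the family, and each member's
adjusted p counts how often that maximum reaches its own |T_obs|.
Adjusted p dominates raw p by construction. Families must mix only
comparably scaled statistics (all t, or all ρ); the
cluster x scale correlation family shares one subject permutation per
reshuffle (`perm_spearman_family`).

## First-level GLM

- **HRF**: canonical double gamma — gamma density with shape 6, scale 1
  (peak ~5 s) minus 1/6 of a gamma with shape 16, scale 1 (undershoot),
  sampled over 32 s and scaled to unit peak.
- **Design**: per condition, a block boxcar on a fine grid (tr/10)
  convolved discretely with the HRF and sampled at volume times;
  temporal derivative columns are first differences (zero at the first
  volume). Rest is the implicit baseline; an intercept is appended at
  fit time, so dof = T − rank(design + intercept).
- **High-pass**: Gaussian-weighted running-line fit (SD 45 s ≈ 0.022 Hz
  cutoff) subtracted pointwise, series mean restored. The filter is one
  smoother matrix, and the **same matrix is applied to the design
  columns** — filtering only the data leaves paradigm-locked residual
  trends that are shared across subjects and masquerade as group-level
  activation (observed on null contrasts during development of the
  synthetic replica).
- **Smoothing**: per-volume Gaussian, sigma = FWHM / (2·sqrt(2·ln 2)) in
  mm, anisotropic voxel sizes respected; default FWHM 6 mm.
- **Fit**: ordinary least squares per voxel. Autocorrelation
  prewhitening is deliberately not implemented: OLS keeps the
  normal-equations oracle exact, and the group-level permutation tests
  do not rely on first-level variance estimates. Varcopes
  (residual_variance · c'(X'X)⁻¹c) matter only for the fixed-effects
  weighting across runs (inverse-variance; zero-varcope voxels fall back
  to the plain average with an imputed variance).
- **Contrasts**: each emotion weighted +1 against −1/3 on each of the
  three pattern conditions (derivatives weighted 0).

## Group inference

Voxelwise t maps (one-sample via subject sign flips pooled across
groups; two-sample via group-label reshuffles, direction a − b) are
enhanced with TFCE: E = 0.5, H = 2, 26-connectivity, threshold step
dh = max statistic / 100 recomputed per map (including per permuted
map), with midpoint heights (h − dh/2) in the discrete sum so the
single-voxel closed form ∫ h² dh = 1/3 is met to 0.01% at dh = 0.01.
Negative effects get a second pass on the negated map. The
implementation inserts voxels once into a union-find while sweeping
thresholds downward (numba-accelerated) and is tested to agree with
per-threshold relabeling to machine precision. Familywise-corrected
voxel p-values use the permutation distribution of the map-wide maximum
|TFCE|. Significant voxels (FWE p ≤ α = 0.05) are grouped into
connected clusters (same connectivity); cluster tables report size, peak
(0-based voxel indices and mm via the affine) and minimum FWE p, and
per-subject cluster means feed the correlation stage.

## Synthetic data: what it emulates, and what it does not

- **Cohort**: group-typical DASS-21 profiles (clipped integer normals;
  control depression capped below the "mild" cut-off of 12, depressed at
  or above the "moderate" cut-off of 14 — the same inequalities the
  screening stage enforces, read literally, leaving scores 12–13
  unacceptable to both groups), ages 18–65, sex proportions matching the
  published table.
- **Paradigm**: 2 runs x 16 blocks of 16.2 s; happy and horizontal six
  blocks total, the rest five; faces and patterns strictly alternate;
  equal rest before each block sized so blocks + rests exactly fill
  168 volumes x 3 s per run (the published trial timing is internally
  inconsistent with the block length, so individual trials are not
  modelled — the GLM consumes block boxcars only).
- **Behavior**: per group/condition means at realistic n-back magnitudes
  (accuracy ~0.70–0.80, RT ~670–820 ms, faces slower than patterns)
  plus a subject random intercept (SD 0.12 / 90 ms) and residual noise
  (SD 0.08 / 55 ms) — the minimal structure a mixed ANOVA assumes.
- **BOLD**: the GLM's own forward model (block boxcars x double-gamma
  HRF) with baseline condition amplitudes everywhere in an ellipsoidal
  brain mask, extra group-dependent happy amplitude inside a cubic
  effect mask, optional per-subject amplitude scaling (used to inject a
  monotone link to a clinical score), baseline offset 100, stationary
  AR(1) Gaussian noise (phi = 0.3, SD 1) and a per-voxel linear drift
  whose amplitude scales with the noise SD (so a noiseless simulation is
  exactly the design prediction).

Not emulated: head motion, physiological noise, spatial autocorrelation
of the noise field, distortion/registration error, trial-level stimulus
variability, non-Gaussian RT distributions. Passing recovery tests
therefore demonstrate that the statistical machinery is correct and
calibrated under its own assumptions, not that the pipeline is robust to
real-scanner artifacts (the original study handled those with
human-in-the-loop preprocessing that is out of scope here).

**Geometry of the scaled-down replica.** Recovery studies use a 16^3
(pipeline default 12^3) grid with voxel size chosen as 190 mm / grid
size (~12 mm), i.e. a whole brain at reduced resolution rather than a
3 mm patch; this keeps mm-specified preprocessing (6 mm smoothing)
physically meaningful and the effect cube (side ~ grid/4) from being
smeared across its neighbourhood. `gen_bold`'s own default voxel size
remains 3 mm, matching the acquisition it mimics.

## Numerical choices and degenerate inputs

- Ranks use midranks for ties throughout.
- Constant vectors: two-sample t on constant pooled data and Spearman on
  constant columns raise; all-zero paired differences return p = 1 with
  a warning; zero-variance voxels get t = 0 with a warning; constant
  cluster-mean or scale columns are skipped from correlation families.
- Enumeration cut-off 20,000 arrangements: exactness where affordable
  (C(27, 14) and 2^27 style spaces fall back to sampling).
- Seeds: a single global seed derives every stage seed as SHA-256 of
  "seed:stage" mod 2^31; identical config + seed reproduce identical
  outputs bit for bit (hashes recorded in the run manifest).

## Problem sizes used by the bundled checks

Unit oracles run on toy fixtures (enumeration spaces ≤ 20,000; 8^3 TFCE
maps). Calibration uses 200 global-null simulations at R = 500.
Full-replica recovery uses the study's sample sizes (14 vs 13), the full
two-run paradigm, a 16^3 grid and R = 500 over 20 seeds (10 in the
acceptance script). These sizes were chosen so a complete run stays
within minutes on a single CPU while keeping every statistic at the
study's own n.

## Known limitations

- OLS first level (no prewhitening): per-run varcopes are mildly
  miscalibrated under AR(1) noise; group inference is unaffected because
  it permutes subject-level copes.
- The Manly-style ANOVA permutation scheme and the exact definition of
  the correlation-difference null are choices among several defensible
  options; both are documented above and validated by calibration
  simulation rather than by comparison to the original (unavailable)
  analysis scripts.
- TFCE output depends on the dh discretization; per-map dh = max/100
  matches common practice but means enhanced values are comparable only
  within a map (which is all maxT needs).
- The published behavioral statistics (F-obs, post-hoc t-obs, ρ, Δρ
  values) depend on the original raw data and cannot be reproduced
  numerically; the pipeline instead verifies the machinery that produced
  them (exactness, calibration, recovery of known effects).
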