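"""HRF, design construction, preprocessing, OLS fits and contrasts."""

import numpy as np
import pytest

from emonback import glm
from emonback.glm import (
    ContrastSpec,
    DesignMatrix,
    HRFParams,
    build_design,
    compute_cope,
    double_gamma_hrf,
    emotion_contrast,
    fit_glm,
    fixed_effects_combine,
    highpass_filter,
    smooth_volume,
)

from conftest import make_paradigm


# ---------------------------------------------------------------------------
# HRF
# ---------------------------------------------------------------------------

def test_hrf_vanishes_at_origin_and_peaks_at_one():
    h = double_gamma_hrf(tr=0.1)
    assert h[0] == pytest.approx(0.0, abs=1e-12)
    assert h.max() == pytest.approx(1.0)


def test_hrf_peak_location_matches_gamma_mode():
    # gamma(shape=delay/disp, scale=disp) modes at delay - disp = 5 s; the
    # subtracted undershoot shifts the argmax only slightly
    params = HRFParams()
    dt = 0.01
    h = double_gamma_hrf(tr=dt, params=params)
    t_peak = np.argmax(h) * dt
    assert abs(t_peak - (params.peak_delay - params.peak_dispersion)) < 0.1


def test_hrf_invalid_params():
    with pytest.raises(ValueError):
        HRFParams(peak_delay=-1)
    with pytest.raises(ValueError):
        double_gamma_hrf(tr=0)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def test_design_column_count_and_causality(six_condition_paradigm):
    d = build_design(six_condition_paradigm, 0, 130, 1.0)
    assert d.matrix.shape == (130, 12)  # 6 conditions x (main + derivative)
    first_onset = 10.0
    happy = d.matrix[:, d.labels.index("happy")]
    assert np.all(happy[: int(first_onset)] == 0)


def test_design_convolution_matches_direct_summation():
    # direct double-sum oracle on a 10-volume, single-condition toy design
    par = make_paradigm([(2.0, 3.0, "happy")], n_volumes=10, tr=1.0)
    oversample = 10
    with pytest.warns(UserWarning, match="no blocks"):
        d = build_design(par, 0, 10, 1.0, include_derivatives=False, oversample=oversample)
    dt = 1.0 / oversample
    hrf = double_gamma_hrf(1.0, oversample=oversample)
    n_fine = 100
    boxcar = np.array([1.0 if 2.0 <= tau * dt < 5.0 else 0.0 for tau in range(n_fine)])
    expected = np.empty(10)
    for v in range(10):
        t_idx = v * oversample
        acc = 0.0
        for tau in range(n_fine):
            lag = t_idx - tau
            if 0 <= lag < len(hrf):
                acc += boxcar[tau] * hrf[lag] * dt
        expected[v] = acc
    assert np.allclose(d.matrix[:, 0], expected, atol=1e-12)


def test_design_missing_condition_dropped_with_warning(six_condition_paradigm):
    par = make_paradigm([(5.0, 8.0, "happy"), (20.0, 8.0, "vertical")],
                        n_volumes=50, tr=1.0)
    with pytest.warns(UserWarning, match="sad"):
        d = build_design(par, 0, 50, 1.0)
    assert "sad" in d.dropped
    assert "happy" in d.labels


def test_design_derivative_is_lagged_difference(six_condition_paradigm):
    d = build_design(six_condition_paradigm, 0, 130, 1.0)
    main = d.matrix[:, d.labels.index("happy")]
    deriv = d.matrix[:, d.labels.index("happy_derivative")]
    assert deriv[0] == 0.0
    assert np.allclose(deriv[1:], np.diff(main))


# ---------------------------------------------------------------------------
# high-pass filter
# ---------------------------------------------------------------------------

def test_highpass_removes_linear_trend():
    t = np.arange(100) * 3.0
    series = 2.0 + 0.05 * t
    out = highpass_filter(series, sigma_s=45.0, tr=3.0)
    assert np.allclose(out, np.full(100, series.mean()), atol=1e-6)


def test_highpass_preserves_fast_sinusoid():
    tr = 3.0
    t = np.arange(200) * tr
    freq = 0.1  # well above the ~0.022 Hz cutoff
    series = np.sin(2 * np.pi * freq * t)
    out = highpass_filter(series, sigma_s=45.0, tr=tr)
    # compare amplitude on the central section (edges see half windows)
    mid = slice(30, 170)
    amp_ratio = np.dot(out[mid], series[mid]) / np.dot(series[mid], series[mid])
    assert abs(amp_ratio - 1.0) < 0.05


def test_highpass_constant_series_unchanged():
    series = np.full(50, 7.5)
    assert np.allclose(highpass_filter(series, 45.0, 3.0), series)


def test_highpass_linearity(rng):
    x = rng.normal(size=120)
    y = rng.normal(size=120)
    lhs = highpass_filter(2.0 * x + 3.0 * y, 45.0, 3.0)
    rhs = 2.0 * highpass_filter(x, 45.0, 3.0) + 3.0 * highpass_filter(y, 45.0, 3.0)
    assert np.allclose(lhs, rhs, atol=1e-10)


def test_highpass_invalid_sigma():
    with pytest.raises(ValueError):
        highpass_filter(np.zeros(10), sigma_s=0.0)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_smooth_zero_fwhm_is_identity(rng):
    vol = rng.normal(size=(6, 6, 6))
    assert np.array_equal(smooth_volume(vol, 0.0), vol)


def test_smooth_impulse_mass_conserved():
    vol = np.zeros((15, 15, 15))
    vol[7, 7, 7] = 3.0
    out = smooth_volume(vol, fwhm_mm=6.0, voxel_dims=(3.0, 3.0, 3.0))
    assert out.sum() == pytest.approx(3.0, rel=1e-6)


def test_smooth_impulse_matches_explicit_kernel():
    sigma_mm = 6.0 / (2 * np.sqrt(2 * np.log(2)))
    sigma_vox = sigma_mm / 3.0
    radius = int(4.0 * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-0.5 * (x / sigma_vox) ** 2)
    k1 /= k1.sum()
    vol = np.zeros((15, 15, 15))
    vol[7, 7, 7] = 1.0
    out = smooth_volume(vol, 6.0, (3.0, 3.0, 3.0))
    expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    sl = slice(7 - radius, 7 + radius + 1)
    assert np.allclose(out[sl, sl, sl], expected, atol=1e-8)


def test_smooth_anisotropic_voxels_narrow_along_thick_axis():
    vol = np.zeros((15, 15, 15))
    vol[7, 7, 7] = 1.0
    out = smooth_volume(vol, 6.0, voxel_dims=(1.0, 1.0, 4.0))
    assert out[7, 7, 8] < out[7, 8, 7]  # less spread across thick voxels


# ---------------------------------------------------------------------------
# GLM fit, contrasts, fixed effects
# ---------------------------------------------------------------------------

def design_from_matrix(X, labels, tr=1.0):
    return DesignMatrix(X, labels, tr)


def test_fit_recovers_noiseless_betas(six_condition_paradigm, rng):
    d = build_design(six_condition_paradigm, 0, 130, 1.0, include_derivatives=False)
    betas_true = rng.normal(size=(7, d.matrix.shape[1]))
    data = betas_true @ d.matrix.T + 50.0
    fit = fit_glm(data, d)
    assert np.allclose(fit.betas, betas_true, atol=1e-9)
    assert np.allclose(fit.residual_variance, 0.0, atol=1e-16)


def test_fit_orthogonal_data_gives_zero_betas(rng):
    X = np.zeros((20, 1))
    X[:10, 0] = 1.0
    X[10:, 0] = -1.0  # zero-mean regressor
    d = design_from_matrix(X, ["happy"])
    data = np.ones((3, 20)) * 5.0  # constant: orthogonal to the regressor
    fit = fit_glm(data, d)
    assert np.allclose(fit.betas, 0.0, atol=1e-12)


def test_fit_matches_normal_equations_oracle(rng):
    X = rng.normal(size=(30, 3))
    d = design_from_matrix(X, ["happy", "vertical", "checked"])
    Y = rng.normal(size=(5, 30))
    fit = fit_glm(Y, d)
    Xf = np.column_stack([X, np.ones(30)])
    for v in range(5):
        beta_hat = np.linalg.solve(Xf.T @ Xf, Xf.T @ Y[v])
        assert np.allclose(fit.betas[v], beta_hat[:3], atol=1e-10)
        rss = ((Y[v] - Xf @ beta_hat) ** 2).sum()
        assert fit.residual_variance[v] == pytest.approx(rss / (30 - 4))


def test_fit_rejects_rank_deficient_design():
    X = np.ones((10, 2))
    with pytest.raises(ValueError, match="zero column|rank"):
        fit_glm(np.zeros((2, 10)), design_from_matrix(X, ["a", "b"]))


def test_emotion_contrast_weights(six_condition_paradigm):
    d = build_design(six_condition_paradigm, 0, 130, 1.0)
    spec = emotion_contrast(d, "happy")
    v = spec.vector(d.labels)
    assert v[d.labels.index("happy")] == 1.0
    for p in glm.PATTERN_CONDITIONS:
        assert v[d.labels.index(p)] == pytest.approx(-1.0 / 3.0)
        assert v[d.labels.index(f"{p}_derivative")] == 0.0
    assert v.sum() == pytest.approx(0.0)


def test_emotion_contrast_missing_pattern_errors():
    par = make_paradigm([(5.0, 8.0, "happy"), (20.0, 8.0, "vertical"),
                         (35.0, 8.0, "horizontal")], n_volumes=60, tr=1.0)
    with pytest.warns(UserWarning):
        d = build_design(par, 0, 60, 1.0)
    with pytest.raises(ValueError, match="checked"):
        emotion_contrast(d, "happy")


def test_cope_hand_arithmetic(six_condition_paradigm):
    d = build_design(six_condition_paradigm, 0, 130, 1.0, include_derivatives=False)
    betas = np.zeros((1, 6))
    betas[0, d.labels.index("happy")] = 2.0
    for p in glm.PATTERN_CONDITIONS:
        betas[0, d.labels.index(p)] = 1.0
    fit = glm.GLMFit(betas, np.array([2.0]), dof=100, labels=list(d.labels))
    pair = compute_cope(fit, emotion_contrast(d, "happy"), d)
    assert pair.cope[0] == pytest.approx(1.0)  # 2 - mean(1,1,1)
    assert pair.varcope[0] >= 0


def test_varcope_matches_explicit_matrix_oracle(rng):
    X = rng.normal(size=(40, 2))
    d = design_from_matrix(X, ["happy", "vertical"])
    Y = rng.normal(size=(4, 40))
    fit = fit_glm(Y, d)
    spec = ContrastSpec({"happy": 1.0, "vertical": -1.0})
    pair = compute_cope(fit, spec, d)
    Xf = np.column_stack([X, np.ones(40)])
    c = np.array([1.0, -1.0, 0.0])
    quad = c @ np.linalg.inv(Xf.T @ Xf) @ c
    assert np.allclose(pair.varcope, fit.residual_variance * quad)
    assert np.allclose(pair.cope, fit.betas @ np.array([1.0, -1.0]))


def test_fixed_effects_equal_runs_halves_variance():
    cp = glm.CopePair(np.array([2.0, -1.0]), np.array([4.0, 2.0]))
    out = fixed_effects_combine([cp, glm.CopePair(cp.cope.copy(), cp.varcope.copy())])
    assert np.allclose(out.cope, cp.cope)
    assert np.allclose(out.varcope, cp.varcope / 2)


def test_fixed_effects_single_run_identity():
    cp = glm.CopePair(np.array([1.0]), np.array([3.0]))
    out = fixed_effects_combine([cp])
    assert out.cope[0] == pytest.approx(1.0)
    assert out.varcope[0] == pytest.approx(3.0)


def test_fixed_effects_inverse_variance_hand_case():
    r1 = glm.CopePair(np.array([0.0]), np.array([1.0]))
    r2 = glm.CopePair(np.array([4.0]), np.array([3.0]))
    out = fixed_effects_combine([r1, r2])
    assert out.cope[0] == pytest.approx(1.0)  # (0/1 + 4/3) / (1 + 1/3)
    assert out.varcope[0] == pytest.approx(0.75)


def test_fixed_effects_commutes_with_voxel_permutation(rng):
    c1 = glm.CopePair(rng.normal(size=10), rng.uniform(0.5, 2, 10))
    c2 = glm.CopePair(rng.normal(size=10), rng.uniform(0.5, 2, 10))
    perm = rng.permutation(10)
    direct = fixed_effects_combine([c1, c2]).cope[perm]
    permuted = fixed_effects_combine([
        glm.CopePair(c1.cope[perm], c1.varcope[perm]),
        glm.CopePair(c2.cope[perm], c2.varcope[perm])]).cope
    assert np.allclose(direct, permuted)
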