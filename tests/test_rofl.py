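import numpy as np
import pytest

from roflpli import (
    FitConfig,
    MeasurementSeries,
    NoiseModel,
    PixelParams,
    ROFLModel,
    fit_image,
    fit_pixel,
)
from roflpli import geometry
from roflpli.fourier import extract_modalities
from roflpli.rofl import _FitContext, build_weights, chi_squared, grid_init


def planar_phi(series):
    return float(extract_modalities(series.intensities[0], series.rho).phi)


# ---------------------------------------------------------------- weights

def test_weight_arithmetic_example(acq):
    I = np.full((5, 18), 1250.0)
    series = MeasurementSeries(I, acq.tilt_states, acq.rho)
    w = build_weights(series, 3.0)
    assert w.shape == (5, 18)
    # sigma_N^2 = 6.1667e-4 -> w = 40.27, and identical for a flat profile
    np.testing.assert_allclose(w, 1 / np.sqrt(6.16667e-4), rtol=1e-5)
    np.testing.assert_allclose(build_weights(series, 6.0), w / np.sqrt(2))


def test_weights_finite_for_zero_counts(acq):
    I = np.full((5, 18), 1000.0)
    I[2, 5] = 0.0
    series = MeasurementSeries(I, acq.tilt_states, acq.rho)
    assert np.all(np.isfinite(build_weights(series, 3.0)))


# ------------------------------------------------------------- chi squared

def test_chi_squared_zero_at_truth(make_series, acq):
    series = make_series(45, 30, 0.5)
    w = build_weights(series, 3.0)
    p = PixelParams(np.deg2rad(45), np.deg2rad(30), 0.5)
    assert chi_squared(p, series, w) == pytest.approx(0.0, abs=1e-18)


def test_chi_squared_invariant_under_symmetrization(make_series):
    series = make_series(60, 40, 0.6, noisy=True, seed=1)
    w = build_weights(series, 3.0)
    rng = np.random.default_rng(2)
    for _ in range(20):
        phi_u, alpha_u = rng.uniform(-7, 7, 2)
        d = rng.uniform(-1.5, 1.5)
        (o, d_s) = geometry.symmetrize(geometry.UnboundedOrientation(phi_u, alpha_u), d)
        chi_raw = chi_squared(PixelParams(phi_u, alpha_u, d), series, w)
        chi_sym = chi_squared(PixelParams(o.phi, o.alpha, d_s), series, w)
        assert chi_sym == pytest.approx(chi_raw, rel=1e-9)


def test_chi_squared_ninety_degree_flip_identity(acq):
    """Shifting phi by 90 deg negates the model, so chi2 = 4 sum (w f)^2.

    Exact for the planar view (tilted views couple phi and alpha through
    the stage rotation, so the identity holds only there).
    """
    from roflpli.forward_model import intensity_profile

    truth = PixelParams(np.deg2rad(30), np.deg2rad(10), 0.8)
    planar = [acq.tilt_states[0]]
    prof = intensity_profile(truth, planar[0], acq)
    series = MeasurementSeries(prof[None, :], planar, acq.rho)
    w = build_weights(series, 3.0)
    flipped = PixelParams(truth.phi + np.pi / 2, truth.alpha, truth.d)
    ctx = _FitContext(planar, acq.rho)
    f = ctx.model(truth.vector(), truth.d)
    assert chi_squared(flipped, series, w) == pytest.approx(
        4 * np.sum((w * f) ** 2), rel=1e-9
    )


# ---------------------------------------------------------------- grid init

def test_grid_init_returns_exact_node(make_series):
    # (alpha, d) = (45 deg, 0.75) is a node of the default 6x6 grid
    series = make_series(100, 45, 0.75)
    w = build_weights(series, 3.0)
    p0 = grid_init(series, w, planar_phi(series))
    assert np.rad2deg(p0.alpha) == pytest.approx(45.0, abs=1e-9)
    assert p0.d == pytest.approx(0.75, abs=1e-12)
    assert p0.chi2 == pytest.approx(0.0, abs=1e-12)


def test_grid_init_is_argmin(make_series):
    series = make_series(10, 62, 0.4, noisy=True, seed=3)
    w = build_weights(series, 3.0)
    phi0 = planar_phi(series)
    p0 = grid_init(series, w, phi0)
    cfg = FitConfig()
    ctx = _FitContext(series.tilt_states, series.rho, cfg)
    for a in ctx.alpha_nodes:
        for d in ctx.d_nodes:
            assert p0.chi2 <= chi_squared(PixelParams(phi0, a, d), series, w) + 1e-9


def test_grid_init_resolves_inclination_sign(make_series):
    """Tilted profiles break the +-alpha degeneracy of the planar view."""
    rng = np.random.default_rng(4)
    for _ in range(100):
        alpha = rng.uniform(15, 75) * rng.choice([-1, 1])
        series = make_series(rng.uniform(0, 180), alpha, rng.uniform(0.3, 0.9))
        w = build_weights(series, 3.0)
        p0 = grid_init(series, w, planar_phi(series))
        assert np.sign(p0.alpha) == np.sign(alpha)


# ------------------------------------------------------------------- fits

def test_noise_free_recovery_is_exact(make_series):
    rng = np.random.default_rng(5)
    for _ in range(30):
        phi, alpha = rng.uniform(0, 180), rng.uniform(-85, 85)
        d = rng.uniform(0.05, 1.0)
        p = fit_pixel(make_series(phi, alpha, d))
        truth = PixelParams(np.deg2rad(phi), np.deg2rad(alpha), d)
        assert geometry.acute_angle(p.vector(), truth.vector()) < 1e-6
        assert p.d == pytest.approx(d, abs=1e-6)
        assert p.chi2 == pytest.approx(0.0, abs=1e-10)


def test_in_plane_fiber_recovered_exactly(make_series):
    """alpha = 0 is where single-view inversion is degenerate; tilting fixes it."""
    p = fit_pixel(make_series(45, 0, 0.5))
    assert p.alpha == pytest.approx(0.0, abs=1e-6)
    assert np.rad2deg(p.phi) == pytest.approx(45.0, abs=1e-6)
    assert p.d == pytest.approx(0.5, abs=1e-6)


def test_fit_never_increases_chi2_from_init(make_series):
    for seed in range(10):
        series = make_series(101, -60, 0.5, noisy=True, seed=seed)
        res = ROFLModel(series, gain=3.0).fit()
        assert res.chi2 <= res.chi2_init + 1e-12
        assert 0 <= res.phi < np.pi
        assert -np.pi / 2 <= res.alpha <= np.pi / 2
        assert res.d >= 0


def test_noisy_fit_goodness(make_series):
    """Steep noisy pixel: the fitted curves explain most of the variance."""
    rsq = []
    for seed in range(5):
        series = make_series(101, -60, 0.5, noisy=True, seed=100 + seed)
        res = ROFLModel(series, gain=3.0).fit()
        rsq.append(res.r_squared)
    assert np.mean(rsq) > 0.9


def test_result_summary_and_uncertainties(make_series):
    res = ROFLModel(make_series(45, 30, 0.5, noisy=True, seed=9), gain=3.0).fit()
    text = res.summary()
    assert "phi [deg]" in text and "R^2" in text
    se = res.bse()
    assert se.shape == (3,) and np.all(se > 0)
    assert res.df_resid == 5 * 18 - 3


def test_fit_beats_dense_brute_force_grid(acq, make_series):
    """LM refinement must reach a lower chi2 than a 91 x 46 x 90 grid search."""
    ctx = _FitContext(acq.tilt_states, acq.rho)
    phis = np.linspace(0, np.pi, 91, endpoint=False)
    alphas = np.linspace(-np.pi / 2, np.pi / 2, 46)
    ds = np.linspace(0.02, 1.0, 90)
    pp, aa, dd = np.meshgrid(phis, alphas, ds, indexing="ij")
    pp, aa, dd = pp.ravel(), aa.ravel(), dd.ravel()
    f_grid = np.empty((pp.size, 5, 18))
    for lo in range(0, pp.size, 50_000):
        hi = min(lo + 50_000, pp.size)
        v = geometry.unit_vectors(pp[lo:hi], aa[lo:hi])
        f_grid[lo:hi] = ctx.model(v, dd[lo:hi])
    rng = np.random.default_rng(6)
    for k in range(20):
        series = make_series(
            rng.uniform(0, 180), rng.uniform(-80, 80), rng.uniform(0.1, 0.9),
            noisy=True, seed=int(rng.integers(1 << 30)),
        )
        w = build_weights(series, 3.0)
        i_n = series.normalized()
        chi2_grid = (((f_grid - i_n) * w) ** 2).sum(axis=(1, 2)).min()
        res = ROFLModel(series, gain=3.0).fit()
        assert res.chi2 <= chi2_grid + 1e-9


# ------------------------------------------------------------------ images

def _phantom_stack(acq, truth, shape=(8, 8), seed=0, corrupt=None):
    from roflpli.forward_model import simulate_series
    from roflpli.io import Stack
    from roflpli.noise import sample_counts

    clean = simulate_series(truth, acq)
    stack = np.tile(clean[:, :, None, None], (1, 1) + shape).astype(float)
    rng = np.random.default_rng(seed)
    stack = sample_counts(stack, acq.gain, rng).astype(float)
    if corrupt is not None:
        j, i, r, c = corrupt
        stack[j, i, r, c] *= 3.0  # a dust particle at one rotation angle
    return Stack(stack, acq.tilt_states, acq.rho)


def test_fit_image_recovers_uniform_phantom(acq):
    truth = PixelParams(np.deg2rad(45), np.deg2rad(30), 0.5)
    maps = fit_image(_phantom_stack(acq, truth), noise=NoiseModel(3.0))
    assert all(np.isfinite(maps[k]).all() for k in maps)
    v = geometry.unit_vectors(maps["direction"], maps["inclination"])
    gamma = np.rad2deg(np.arccos(np.clip(np.abs(v @ truth.vector()), -1, 1)))
    assert gamma.mean() < 5.0
    assert np.abs(maps["thickness"] - 0.5).mean() < 0.1


def test_fit_image_worker_count_is_irrelevant(acq):
    truth = PixelParams(np.deg2rad(120), np.deg2rad(-20), 0.7)
    stack = _phantom_stack(acq, truth, shape=(4, 4), seed=1)
    m1 = fit_image(stack, n_workers=1)
    m2 = fit_image(stack, n_workers=2)
    for k in m1:
        np.testing.assert_array_equal(m1[k], m2[k])


def test_chi2_map_flags_dust_without_breaking_parameters(acq):
    truth = PixelParams(np.deg2rad(60), np.deg2rad(25), 0.6)
    stack = _phantom_stack(acq, truth, seed=2, corrupt=(0, 7, 3, 3))
    maps = fit_image(stack, noise=NoiseModel(3.0))
    chi2 = maps["chi2"]
    others = np.delete(chi2.ravel(), 3 * 8 + 3)
    assert chi2[3, 3] > 5 * np.median(others)
    v = geometry.unit_vectors(maps["direction"][3, 3], maps["inclination"][3, 3])
    gamma = np.rad2deg(np.arccos(min(abs(float(v @ truth.vector())), 1.0)))
    assert gamma < 5.0
    assert abs(maps["thickness"][3, 3] - 0.6) < 0.1


def test_fit_image_masks_dark_background(acq):
    truth = PixelParams(np.deg2rad(45), np.deg2rad(10), 0.7)
    stack = _phantom_stack(acq, truth, shape=(4, 4), seed=3)
    stack.intensities[:, :, 0, 0] = 1.0  # opaque pixel
    maps = fit_image(stack, noise=NoiseModel(3.0))
    assert np.isnan(maps["direction"][0, 0])
    assert np.isfinite(maps["direction"][1:, :]).all()
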