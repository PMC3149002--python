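"""Marginal frequency posterior: oracle equivalence, invariances, estimator."""

import numpy as np
import pytest
from sklearn.base import clone

from bsafreq.basis import ModelSpec
from bsafreq.core import (
    BayesianSpectrum,
    _explained_fraction,
    estimate_amplitudes,
    estimate_noise_snr,
    fine_sample,
    log_posterior,
    refine_peak,
    scan,
)
from bsafreq.simulate import fixture
from bsafreq.timeseries import TimeSeries


def quadrature_log_marginal(ts, omega):
    """Brute-force marginal of one sin/cos pair, up to an omega-independent
    constant: numeric integral over the two amplitudes and over sigma
    (bounded Jeffreys prior).

    The closed form assigns uniform priors to the amplitudes of the
    *orthonormalised* model functions, so the raw-amplitude integral is
    multiplied by the Jacobian sqrt(det G) of that change of variables.
    The amplitude grid is centred on the least-squares solution so the
    narrow high-likelihood region is resolved.
    """
    t, d = ts.times, ts.values
    design = np.column_stack([np.sin(omega * t), np.cos(omega * t)])
    gram = design.T @ design
    proj = design.T @ d
    dd = float(d @ d)
    center = np.linalg.solve(gram, proj)
    # graded grid: fine where the likelihood is sharp at small sigma, wide
    # tails for the broad-amplitude mass at large sigma
    core = np.linspace(-2.0, 2.0, 401)
    tail = np.linspace(2.0, 24.0, 111)[1:]
    offsets = np.concatenate([-tail[::-1], core, tail])
    a = center[0] + offsets
    b = center[1] + offsets
    aa, bb = np.meshgrid(a, b, indexing="ij")
    sse = (
        dd - 2 * aa * proj[0] - 2 * bb * proj[1]
        + aa**2 * gram[0, 0] + 2 * aa * bb * gram[0, 1] + bb**2 * gram[1, 1]
    )
    u = np.linspace(np.log(0.01), np.log(100.0), 161)  # log sigma
    n = t.size
    log_slices = np.empty(u.size)
    for i, ui in enumerate(u):
        li = -n * ui - 0.5 * sse * np.exp(-2 * ui)
        peak_i = li.max()
        inner = np.trapezoid(np.exp(li - peak_i), b, axis=1)
        log_slices[i] = peak_i + np.log(np.trapezoid(inner, a))
    peak = log_slices.max()
    du = u[1] - u[0]
    total = np.exp(log_slices - peak).sum() * du
    jacobian = 0.5 * np.linalg.slogdet(gram)[1]
    return peak + np.log(total) + jacobian


class TestQuadratureOracle:
    def test_posterior_matches_brute_force_integral(self):
        """log-posterior differences across omega equal the oracle's."""
        rng = np.random.default_rng(42)
        n = 8
        t = np.sort(rng.uniform(0.0, 14.0, n))
        d = np.sin(0.6 * t) + 0.2 * rng.normal(size=n)
        ts = TimeSeries(t, d)
        spec = ModelSpec(1, -1)
        omegas = [0.25, 0.45, 0.6, 0.8, 1.1]
        oracle = np.array([quadrature_log_marginal(ts, w) for w in omegas])
        ours = np.array([log_posterior(ts, spec, w) for w in omegas])
        diff = (oracle - oracle[0]) - (ours - ours[0])
        assert np.abs(diff).max() < 2e-3

    def test_multiple_instances(self):
        """Oracle equivalence holds across independent small instances."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(6, 11))
            t = np.sort(rng.uniform(0.0, 12.0, n))
            t += np.arange(n) * 1e-3  # guard against coincident times
            d = np.sin(0.5 * t + rng.uniform(0, 2 * np.pi))
            d += 0.3 * rng.normal(size=n)
            ts = TimeSeries(t, d)
            spec = ModelSpec(1, -1)
            omegas = [0.3, 0.5, 0.9]
            oracle = np.array([quadrature_log_marginal(ts, w) for w in omegas])
            ours = np.array([log_posterior(ts, spec, w) for w in omegas])
            diff = (oracle - oracle[0]) - (ours - ours[0])
            assert np.abs(diff).max() < 5e-3, f"seed {seed}"


class TestExplainedFraction:
    def test_jit_matches_reference_route(self):
        """Compiled kernel agrees with the explicit orthonormal-basis route."""
        from bsafreq.basis import design_stats

        _, ts = fixture("table2_row9", seed=3)
        for spec, w in [
            (ModelSpec(1, -1), [0.5]),
            (ModelSpec(1, 2), [0.37]),
            (ModelSpec(2, 1), [0.3, 0.5]),
        ]:
            n, m, frac = _explained_fraction(ts, spec, np.array(w))
            stats = design_stats(ts, spec, np.array(w))
            ref = stats.m * stats.h2_bar / (stats.n * stats.d2_bar)
            assert frac == pytest.approx(ref, abs=1e-12)

    def test_perfect_fit_capped(self):
        t = np.arange(60.0)
        ts = TimeSeries(t, np.sin(0.5 * t))
        val = log_posterior(ts, ModelSpec(1, -1), 0.5)
        assert np.isfinite(val)
        cap = 0.5 * (60 - 2) * (-np.log(np.finfo(float).eps))
        assert val == pytest.approx(cap)


class TestScanRefine:
    def test_scan_and_refine_locate_the_tone(self):
        _, ts = fixture("table2_row2", seed=5)
        spec = ModelSpec(1, -1)
        grid, logp, coarse = scan(ts, spec, 0.05, 1.5, 500)
        assert abs(coarse - 0.5) < 0.01
        mode = refine_peak(ts, spec, coarse, step=(1.5 - 0.05) / 499)
        assert abs(mode[0] - 0.5) < 0.005

    def test_refine_respects_bounds(self):
        _, ts = fixture("table2_row2", seed=5)
        spec = ModelSpec(1, -1)
        mode = refine_peak(ts, spec, 0.45, step=0.01, bounds=(0.4, 0.47))
        assert 0.4 <= mode[0] <= 0.47

    def test_scan_rejects_bad_args(self):
        _, ts = fixture("table2_row2", seed=5)
        with pytest.raises(ValueError):
            scan(ts, ModelSpec(2, -1), 0.05, 1.5)
        with pytest.raises(ValueError):
            scan(ts, ModelSpec(1, -1), 1.5, 0.05)


class TestFineSample:
    def test_density_normalised_and_unimodal(self):
        _, ts = fixture("table2_row2", seed=5)
        spec = ModelSpec(1, -1)
        fine = fine_sample(ts, spec, np.array([0.5]))
        area = np.trapezoid(fine["density"], fine["grid"])
        assert area == pytest.approx(1.0, rel=1e-6)
        assert fine["n_modes"] == 1
        assert fine["sd"][0] > 0


class TestNoiseAndAmplitudes:
    def test_noise_estimate_tracks_injected_sigma(self):
        _, ts = fixture("table2_row2", seed=7)  # e_a = 10% -> sigma = 0.1
        sigma, snr = estimate_noise_snr(ts, ModelSpec(1, -1), np.array([0.5]))
        assert sigma == pytest.approx(0.1, rel=0.3)
        assert snr == pytest.approx(np.sqrt(0.5) / 0.1, rel=0.3)

    def test_amplitudes_recover_unit_sine(self):
        t = np.arange(100.0) * 3.0
        ts = TimeSeries(t, np.sin(0.5 * t))
        coef = estimate_amplitudes(ts, ModelSpec(1, -1), np.array([0.5]))
        np.testing.assert_allclose(coef, [1.0, 0.0], atol=1e-10)


class TestAmplitudeScalingInvariance:
    def test_mode_invariant_noise_scales(self):
        _, ts = fixture("table2_row2", seed=11)
        est = BayesianSpectrum().fit(ts)
        est_k = BayesianSpectrum().fit(ts.scaled(37.5))
        assert est_k.omega_[0] == pytest.approx(est.omega_[0], abs=1e-8)
        assert est_k.noise_sigma_ == pytest.approx(37.5 * est.noise_sigma_,
                                                   rel=1e-8)
        assert est_k.snr_ == pytest.approx(est.snr_, rel=1e-8)


class TestEstimatorAPI:
    def test_params_round_trip_and_clone(self):
        est = BayesianSpectrum(n_grid=123, background_order=2)
        params = est.get_params()
        assert params["n_grid"] == 123
        est2 = clone(est)
        assert est2.get_params() == params
        est2.set_params(n_grid=50)
        assert est2.n_grid == 50

    def test_fit_accepts_arrays_and_timeseries(self):
        _, ts = fixture("table2_row2", seed=5)
        a = BayesianSpectrum().fit(ts)
        b = BayesianSpectrum().fit(ts.times, ts.values)
        assert a.omega_[0] == b.omega_[0]
        assert b.period_[0] == pytest.approx(2 * np.pi / b.omega_[0])

    def test_score_is_log_posterior_at_mode(self):
        _, ts = fixture("table2_row2", seed=5)
        est = BayesianSpectrum().fit(ts)
        assert est.score(ts) == pytest.approx(
            log_posterior(ts, est.spec_, est.omega_)
        )
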