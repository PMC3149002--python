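"""Design matrices, orthonormalisation and the residual identity."""

import numpy as np
import numpy.polynomial.legendre as npleg
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bsafreq.basis import (
    DegenerateBasisError,
    ModelSpec,
    design_stats,
    legendre_time_map,
    make_design,
    orthonormalize,
)
from bsafreq.timeseries import TimeSeries


def random_ts(seed, n=40, jitter=0.3):
    rng = np.random.default_rng(seed)
    t = np.arange(n) * 1.0 + jitter * rng.uniform(-0.4, 0.4, n)
    d = rng.normal(size=n)
    return TimeSeries(np.sort(t), d)


class TestModelSpec:
    def test_counts(self):
        spec = ModelSpec(2, 1)
        assert spec.m_signal == 4
        assert spec.m_background == 2
        assert spec.m == 6
        assert ModelSpec(0, 2).m == 3
        assert ModelSpec(1, -1).m == 2

    def test_invalid(self):
        with pytest.raises(ValueError):
            ModelSpec(-1, 0)
        with pytest.raises(ValueError):
            ModelSpec(1, -2)
        with pytest.raises(ValueError):
            ModelSpec(0, -1)  # no model functions at all


class TestDesign:
    def test_legendre_columns_match_numpy_oracle(self):
        ts = random_ts(0)
        spec = ModelSpec(0, 3)
        design = make_design(spec, np.empty(0), ts.times)
        tau = legendre_time_map(ts.times)
        for order in range(4):
            coeffs = np.zeros(order + 1)
            coeffs[order] = 1.0
            np.testing.assert_allclose(
                design[:, order], npleg.legval(tau, coeffs), atol=1e-12
            )

    def test_sinusoid_columns(self):
        ts = random_ts(1)
        design = make_design(ModelSpec(1, -1), np.array([0.37]), ts.times)
        np.testing.assert_allclose(design[:, 0], np.sin(0.37 * ts.times))
        np.testing.assert_allclose(design[:, 1], np.cos(0.37 * ts.times))

    def test_duplicate_frequency_rejected(self):
        ts = random_ts(2)
        with pytest.raises(DegenerateBasisError):
            make_design(ModelSpec(2, -1), np.array([0.4, 0.4]), ts.times)

    def test_overparameterised_rejected(self):
        ts = TimeSeries(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            make_design(ModelSpec(2, 1), np.array([0.3, 0.5]), ts.times)


class TestOrthonormalize:
    @given(st.integers(0, 200))
    def test_orthonormal_on_jittered_grids(self, seed):
        ts = random_ts(seed, n=30)
        design = make_design(ModelSpec(1, 2), np.array([0.3]), ts.times)
        h, chol = orthonormalize(design)
        np.testing.assert_allclose(h.T @ h, np.eye(h.shape[1]), atol=1e-8)
        # design = H L^T reconstructs exactly
        np.testing.assert_allclose(h @ chol.T, design, atol=1e-8)

    def test_degenerate_raises(self):
        t = np.arange(50.0)
        design = np.column_stack([np.sin(0.3 * t), np.sin(0.3 * t) + 1e-14])
        with pytest.raises(DegenerateBasisError):
            orthonormalize(design)


class TestResidualIdentity:
    @given(
        st.integers(0, 10**6),
        st.integers(1, 2),
        st.integers(-1, 2),
    )
    def test_matches_least_squares(self, seed, r, bg):
        """N*d2_bar - m*h2_bar equals the least-squares residual SS."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 50))
        ts = random_ts(seed + 1, n=n)
        omegas = np.sort(rng.uniform(0.1, 1.4, r))
        if r == 2 and omegas[1] - omegas[0] < 0.05:
            omegas[1] = omegas[0] + 0.05
        spec = ModelSpec(r, bg)
        stats = design_stats(ts, spec, omegas)
        design = make_design(spec, omegas, ts.times)
        _, res, _, _ = np.linalg.lstsq(design, ts.values, rcond=None)
        expected = float(res[0]) if res.size else float(
            np.sum((ts.values - design @ np.linalg.lstsq(
                design, ts.values, rcond=None)[0]) ** 2)
        )
        assert stats.residual_ss == pytest.approx(expected, rel=1e-8, abs=1e-8)
        # and the pieces are what they claim to be
        assert stats.n * stats.d2_bar == pytest.approx(
            float(ts.values @ ts.values), rel=1e-12
        )
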