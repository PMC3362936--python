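"""Covariance-function trajectories: worked values and shape properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tolgen.covfun import (
    GenCov2,
    correlation_with_healthy,
    trajectory_ratios,
    trajectory_variance,
    variance_ratios,
)

# intercept/slope genetic components of the tolerance reaction norm
G_TOL = GenCov2.from_correlation(10640.0, 57.8, -0.30)


class TestTrajectoryVariance:
    def test_value_at_healthy_point_is_intercept_variance(self):
        assert trajectory_variance(G_TOL, 0.0) == pytest.approx(10640.0)

    def test_value_at_severity_17_5(self):
        # frozen from the quadratic form evaluated by hand:
        # 10640 + 2*17.5*(-0.30*sqrt(10640*57.8)) + 17.5^2*57.8
        expected = 10640.0 + 2 * 17.5 * (-0.30 * np.sqrt(10640.0 * 57.8)) \
            + 17.5**2 * 57.8
        assert expected == pytest.approx(20107.2, abs=0.5)
        assert trajectory_variance(G_TOL, 17.5) == pytest.approx(expected)

    def test_constant_when_slope_block_zero(self):
        g = GenCov2(100.0, 0.0, 0.0)
        t = np.linspace(0, 20, 11)
        assert np.allclose(trajectory_variance(g, t), 100.0)

    def test_negative_severity_rejected(self):
        with pytest.raises(ValueError):
            trajectory_variance(G_TOL, -1.0)

    @given(
        st.floats(min_value=1.0, max_value=1e5),
        st.floats(min_value=0.01, max_value=1e3),
        st.floats(min_value=-0.99, max_value=0.99),
        st.floats(min_value=0.0, max_value=50.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_nonnegative_for_any_psd_block(self, v0, v1, r, t):
        g = GenCov2.from_correlation(v0, v1, r)
        assert trajectory_variance(g, t) >= -1e-9 * v0


class TestCorrelationWithHealthy:
    def test_unity_at_healthy_point(self):
        assert correlation_with_healthy(G_TOL, 0.0) == pytest.approx(1.0)

    def test_value_at_heart_ratio_46_5(self):
        # severity 46.5% - 29% = 17.5 on the plateau scale
        assert round(correlation_with_healthy(G_TOL, 17.5), 2) == 0.45

    def test_zero_covariance_closed_form(self):
        g = GenCov2(100.0, 4.0, 0.0)
        t = np.linspace(0.0, 30.0, 50)
        r = correlation_with_healthy(g, t)
        expected = 10.0 / np.sqrt(100.0 + t**2 * 4.0)
        assert np.allclose(r, expected)
        assert np.all(np.diff(r) <= 0)
        assert np.all(r > 0)

    def test_monotone_decrease_under_negative_covariance(self):
        t = np.linspace(0.0, 20.0, 200)
        r = correlation_with_healthy(G_TOL, t)
        assert np.all(np.diff(r) < 0)
        assert np.all(np.abs(r) <= 1.0 + 1e-12)

    def test_zero_intercept_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_with_healthy(GenCov2(0.0, 1.0, 0.0), 1.0)

    @given(
        st.floats(min_value=1.0, max_value=1e5),
        st.floats(min_value=0.01, max_value=1e3),
        st.floats(min_value=-0.99, max_value=0.99),
        st.floats(min_value=0.0, max_value=50.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_bounded_by_one(self, v0, v1, r, t):
        g = GenCov2.from_correlation(v0, v1, r)
        assert abs(correlation_with_healthy(g, t)) <= 1.0 + 1e-9


class TestVarianceRatios:
    def test_equal_components_toy(self):
        h2, m2 = variance_ratios(1.0, 1.0, 1.0)
        assert h2 == pytest.approx(1 / 3)
        assert m2 == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "vg, vm, vp, h2, m2",
        [(309.0, 59.3, 946.0, 0.33, 0.06), (12952.0, 2913.0, 73479.0, 0.18, 0.04)],
    )
    def test_body_weight_ratio_values(self, vg, vm, vp, h2, m2):
        got_h2, got_m2 = variance_ratios(vg, vm, vp - vg - vm)
        assert round(got_h2, 2) == h2
        assert round(got_m2, 2) == m2


class TestTrajectoryTable:
    def test_pointwise_decomposition_identity(self):
        m = GenCov2.from_correlation(2771.0, 23.0, -0.26)
        ve = np.array([43805.0, 45000.0, 50000.0, 60000.0, 91000.0])
        out = trajectory_ratios(G_TOL, m, ve)
        assert np.allclose(out.v_p, out.v_g + out.v_m + out.v_e)
        assert ((out.h2 >= 0) & (out.h2 <= 1)).all()
        assert ((out.m2 >= 0) & (out.m2 <= 1)).all()
        assert out.r_with_healthy.iloc[0] == pytest.approx(1.0)
        # grid reported against back-transformed heart ratios 29..49
        assert out.heart_ratio.iloc[0] == 29.0
        assert out.heart_ratio.iloc[-1] == 49.0

    def test_zero_phenotypic_variance_rejected(self):
        g0 = GenCov2(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            trajectory_ratios(g0, g0, np.zeros(5))
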