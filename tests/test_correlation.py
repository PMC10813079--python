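"""Baseline power law, correction-table interpolation, corrected stress."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stenoshear import correlation as corr
from stenoshear.correlation import (
    BETA3_DEFAULTED,
    CLAMPED_VELOCITY,
    CLAMPED_W,
    CLAMPED_Z,
    EXTRAPOLATED_K,
    CorrelationError,
    tables,
)
from stenoshear.geometry import FlowCondition, StenosisGeometry
from stenoshear.ica_case import GEOMETRY as ICA, REFERENCE


class TestTau0:
    @pytest.mark.parametrize(
        "u,expected", [(0.088, 60.3), (0.174, 152.0), (0.451, 548.1)]
    )
    def test_carotid_flow_states(self, u, expected):
        # printed inputs carry rounding, hence the 1% band
        assert corr.tau0(u, 0.29) == pytest.approx(expected, rel=0.01)

    def test_no_stenosis_unit_velocity(self):
        assert corr.tau0(1.0, 1.0) == pytest.approx(24.21)

    def test_occluded_vessel_rejected(self):
        with pytest.raises(CorrelationError):
            corr.tau0(0.1, 0.0)

    @given(st.floats(0.01, 2.0), st.floats(0.05, 1.0))
    @settings(derandomize=True)
    def test_monotone_in_velocity_and_degree(self, u, r):
        eps = 1e-6
        assert corr.tau0(u + eps, r) > corr.tau0(u, r)
        if r + eps <= 1.0:
            assert corr.tau0(u, r + eps) < corr.tau0(u, r)


class TestTableNodeExactness:
    @pytest.mark.parametrize("name,fn", [
        ("beta1", corr.beta1), ("beta2", corr.beta2), ("beta3", corr.beta3),
    ])
    def test_all_printed_nodes_reproduced(self, name, fn):
        table = tables()[name]
        for i, u in enumerate(table.velocity_grid):
            for j, s in enumerate(table.shape_grid):
                value, flags = fn(float(u), float(s))
                assert value == pytest.approx(table.values[i, j], abs=1e-9)
                assert not flags

    @pytest.mark.parametrize("name,fn,ref", [
        ("beta1", corr.beta1, 1.00),
        ("beta2", corr.beta2, 4.17),
        ("beta3", corr.beta3, 1.00),
    ])
    def test_reference_column_is_unity_at_any_velocity(self, name, fn, ref):
        for u in (0.053, 0.08, 0.2, 0.33, 0.529):
            value, _ = fn(u, ref)
            assert value == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "fn,u,s,expected",
        [
            (corr.beta1, 0.053, 0.50, 1.68),
            (corr.beta2, 0.106, 1.04, 1.81),
            (corr.beta3, 0.053, 0.70, 1.36),
            (corr.beta3, 0.318, 0.96, 1.00),
            (corr.beta2, 0.529, 4.17, 1.00),
        ],
    )
    def test_spot_values(self, fn, u, s, expected):
        value, _ = fn(u, s)
        assert value == pytest.approx(expected, abs=1e-9)


class TestInterpolationBehaviour:
    def test_midpoint_queries_stay_within_bracketing_nodes(self):
        """Shape-preserving interpolation never overshoots node values."""
        for name, fn in (("beta1", corr.beta1), ("beta2", corr.beta2),
                         ("beta3", corr.beta3)):
            table = tables()[name]
            for i, u in enumerate(table.velocity_grid):
                for j in range(table.shape_grid.size - 1):
                    mid = 0.5 * (table.shape_grid[j] + table.shape_grid[j + 1])
                    value, _ = fn(float(u), float(mid))
                    lo = min(table.values[i, j], table.values[i, j + 1])
                    hi = max(table.values[i, j], table.values[i, j + 1])
                    assert lo - 1e-12 <= value <= hi + 1e-12

    def test_monotone_decreasing_in_shape_parameter(self):
        """beta1 falls with vessel scale and beta2 with stenosis length."""
        for name, fn in (("beta1", corr.beta1), ("beta2", corr.beta2)):
            table = tables()[name]
            for u in table.velocity_grid:
                sweep = np.linspace(table.shape_grid[0], table.shape_grid[-1], 40)
                values = [fn(float(u), float(s))[0] for s in sweep]
                assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_axis_order_switch_agrees_closely(self):
        for u, s in [(0.08, 0.6), (0.2, 0.9), (0.45, 1.1)]:
            v1, _ = corr.beta1(u, s, velocity_first=True)
            v2, _ = corr.beta1(u, s, velocity_first=False)
            assert v2 == pytest.approx(v1, rel=0.01)

    def test_velocity_clamping_flagged(self):
        low, flags_low = corr.beta2(0.01, 2.0)
        at_edge, _ = corr.beta2(0.053, 2.0)
        assert CLAMPED_VELOCITY in flags_low
        assert low == pytest.approx(at_edge)

    def test_z_clamping(self):
        value, flags = corr.beta2(0.2, 6.0)
        assert value == 1.0 and CLAMPED_Z in flags
        short, flags_short = corr.beta2(0.2, 0.5)
        at_col, _ = corr.beta2(0.2, 1.04)
        assert CLAMPED_Z in flags_short
        assert short == pytest.approx(at_col)

    def test_w_clamping_and_default(self):
        value, flags = corr.beta3(0.2, 0.5)
        at_col, _ = corr.beta3(0.2, 0.70)
        assert CLAMPED_W in flags and value == pytest.approx(at_col)
        default, dflags = corr.beta3(0.2, None)
        assert default == 1.0 and dflags == {BETA3_DEFAULTED}


class TestScaleExtrapolation:
    def test_power_fits_meet_quality_bar(self):
        for fit in corr.beta1_power_fits():
            assert fit.r_squared > 0.99

    @pytest.mark.parametrize(
        "u,published", [(0.088, 0.6179), (0.174, 0.6436), (0.451, 0.6829)]
    )
    def test_carotid_scale_extrapolation(self, u, published):
        """Power-law extrapolation to k≈1.98 recovers the published
        coefficients; the band absorbs the unspecified original fit."""
        k = 7.6 / 3.83
        value, flags = corr.beta1(u, k)
        assert EXTRAPOLATED_K in flags
        assert value == pytest.approx(published, rel=0.05)


class TestTauMax:
    def test_base_geometry_reduces_to_baseline(self):
        g = StenosisGeometry(3.83, 16.0, 0.4, 1.15)
        for u in (0.053, 0.2, 0.529):
            pred = corr.tau_max(g, FlowCondition(mean_velocity_before_stenosis=u))
            assert pred.beta1 == pytest.approx(1.0, abs=1e-9)
            assert pred.beta2 == pytest.approx(1.0, abs=1e-9)
            assert pred.beta3 == pytest.approx(1.0, abs=1e-9)
            assert pred.tau_max == pytest.approx(corr.tau0(u, 0.4))

    def test_product_structure(self):
        pred = corr.tau_max(
            ICA, FlowCondition(mean_velocity_before_stenosis=0.174))
        assert pred.tau_max == pytest.approx(
            pred.tau0 * pred.beta1 * pred.beta2 * pred.beta3, rel=1e-15)
        assert BETA3_DEFAULTED in pred.flags and EXTRAPOLATED_K in pred.flags

    def test_strictly_increasing_in_velocity(self):
        g = StenosisGeometry(5.0, 8.0, 0.35, 1.2)
        us = np.linspace(0.053, 0.529, 30)
        taus = [
            corr.tau_max(g, FlowCondition(mean_velocity_before_stenosis=float(u))).tau_max
            for u in us
        ]
        assert all(a < b for a, b in zip(taus, taus[1:]))


class TestRelativeDeviation:
    @pytest.mark.parametrize(
        "pred,ref,expected",
        [(42.5, 51.6, -17.6), (466.2, 496.7, -6.1), (7.0, 7.0, 0.0)],
    )
    def test_published_comparisons(self, pred, ref, expected):
        assert corr.relative_deviation(pred, ref) == pytest.approx(
            expected, abs=0.05
        )

    def test_rejects_non_positive_reference(self):
        with pytest.raises(CorrelationError):
            corr.relative_deviation(1.0, 0.0)
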