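import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import peaklag as pk
from peaklag import landscapes as ls


class TestMakeBump:
    def test_value_at_center_equals_height(self):
        bump = pk.make_bump(35.0, 2.5, 4, 1.0)
        assert bump(35.0) == pytest.approx(2.5)

    def test_zero_outside_support(self):
        bump = pk.make_bump(40.0, 2.5, 2, 1.0)
        assert bump(42.0) == 0.0

    def test_support_half_width_closed_form(self):
        bump = pk.make_bump(40.0, 2.5, 2, 1.0)
        assert bump.support_half_width == pytest.approx(math.sqrt(2.5))

    @pytest.mark.parametrize("exponent", [1, 3, 0, -2])
    def test_odd_or_nonpositive_exponent_rejected(self, exponent):
        with pytest.raises(ls.ParameterError):
            pk.make_bump(0.0, 1.0, exponent)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ls.ParameterError):
            pk.make_bump(0.0, -1.0, 2)

    @given(center=st.floats(-50, 50), height=st.floats(0.1, 10),
           p_half=st.integers(1, 4), x=st.floats(-80, 80))
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_and_zero_outside_closed_support(self, center, height,
                                                         p_half, x):
        bump = pk.make_bump(center, height, 2 * p_half)
        val = float(bump(x))
        assert val >= 0.0
        if abs(x - center) > bump.support_half_width:
            assert val == 0.0

    def test_continuous_at_support_edge(self):
        bump = pk.make_bump(0.0, 2.0, 2)
        w = bump.support_half_width
        assert bump(w) == pytest.approx(0.0, abs=1e-12)
        assert bump(w - 1e-9) == pytest.approx(0.0, abs=1e-7)


class TestComposeLandscape:
    def test_fig4_value_disjoint_supports(self, fig4_landscape):
        assert fig4_landscape(35.0, 0.0) == pytest.approx(2.0)

    def test_fig8_case2_constructs(self):
        ps = pk.preset("fig8")
        assert ps["landscape"].case_tag == ls.CASE2
        assert ps["landscape"].speed_pair == (-1.2, 1.2)

    def test_empty_component_list_rejected(self):
        with pytest.raises(ls.ParameterError):
            pk.compose_landscape([], 0.5)

    def test_case2_requires_diverging_speeds(self):
        comps = [pk.make_bump(30, 1.0, 2, 1.0), pk.make_bump(50, 1.0, 2, 2.0)]
        with pytest.raises(ls.AssumptionViolation):
            pk.compose_landscape(comps, 0.5, case_tag=ls.CASE2)

    def test_case1_requires_common_speed(self):
        comps = [pk.make_bump(30, 1.0, 2, 1.0), pk.make_bump(50, 1.0, 2, 2.0)]
        with pytest.raises(ls.AssumptionViolation):
            pk.compose_landscape(comps, 0.5, case_tag=ls.CASE1)

    def test_nonpositive_death_rate_warns_not_errors(self):
        with pytest.warns(UserWarning, match="death rate"):
            land = pk.compose_landscape([pk.make_bump(40, 1.0, 2)], -0.5)
        assert land(40.0) == pytest.approx(1.5)

    def test_shift_evaluation(self, single_peak):
        # a(x, t) = bump(x - eps*c*t) - d
        t = 3.0
        shift = single_peak.epsilon * 1.0 * t
        assert single_peak(40.0 + shift, t) == pytest.approx(2.0)

    def test_support_radius(self, fig4_landscape):
        assert fig4_landscape.support_radius == pytest.approx(
            40.0 + math.sqrt(2.5))


class TestValidateAssumptions:
    def test_single_quadratic_passes_with_one_outer_crossing(self, single_peak):
        rep = ls.validate_assumptions(single_peak, 1.0)
        assert rep.all_passed
        a5 = rep["A5_level_crossings"]
        # exactly one crossing left of the peak at 39.5
        assert len(a5.locations) == 1
        assert a5.locations[0] == pytest.approx(39.5, abs=1e-3)

    def test_overrun_speed_fails_level_crossings(self, single_peak):
        rep = ls.validate_assumptions(single_peak, 4.0)
        assert not rep["A5_level_crossings"].passed

    def test_flat_top_fails_finite_maxima(self):
        class FlatTop(ls.FitnessLandscape):
            def __call__(self, x, t=0.0):
                return np.minimum(super().__call__(x, t), 1.5)

        land = FlatTop(components=(pk.make_bump(40, 2.5, 2),), death_rate=0.5,
                       case_tag=ls.CASE1, epsilon=0.1)
        rep = ls.validate_assumptions(land, 1.0)
        assert not rep["A4_finite_maxima"].passed

    @pytest.mark.parametrize("name", ls.PRESET_NAMES)
    def test_all_presets_pass(self, name):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = pk.preset(name)
        c_or_pair = ps.get("c", ps.get("c_pair"))
        rep = ls.validate_assumptions(ps["landscape"], c_or_pair)
        assert rep.all_passed, {k: v.detail for k, v in rep.checks.items()
                                if not v.passed}

    def test_negative_d_warns_in_report(self):
        ps = pk.preset("fig6")
        rep = ls.validate_assumptions(ps["landscape"], ps["c_pair"])
        assert any("d <= 0" in w for w in rep.warnings)


class TestGlobalMaxima:
    def test_fig4_peaks(self, fig4_landscape):
        peaks = pk.global_maxima(fig4_landscape)
        assert [p.location for p in peaks] == pytest.approx([35.0, 40.0])
        assert all(p.value == pytest.approx(2.0) for p in peaks)

    def test_quartic_curvature_zero(self, fig4_landscape):
        peaks = pk.global_maxima(fig4_landscape)
        assert peaks[0].curvature_magnitude == pytest.approx(0.0)

    def test_quadratic_curvature_two(self, fig4_landscape):
        peaks = pk.global_maxima(fig4_landscape)
        assert peaks[1].curvature_magnitude == pytest.approx(2.0)


class TestLaggedOptima:
    def test_quadratic_closed_form(self, single_peak):
        (opt,) = pk.lagged_optima(single_peak, 1.0)
        assert opt.location == pytest.approx(39.5, abs=1e-9)
        assert opt.lagged_fitness == pytest.approx(1.75)

    def test_quartic_closed_form(self):
        land = pk.compose_landscape([pk.make_bump(35, 2.5, 4, 1.0)], 0.5)
        (opt,) = pk.lagged_optima(land, 1.0)
        assert opt.location == pytest.approx(35.0 - 4.0 ** (-0.25), abs=1e-9)

    def test_zero_speed_gives_peak_locations(self, fig4_landscape):
        opts = pk.lagged_optima(fig4_landscape, 0.0)
        assert [o.location for o in opts] == pytest.approx([35.0, 40.0])

    @pytest.mark.parametrize("c", [0.5, 0.1, 0.01])
    def test_small_speed_converges_to_peaks(self, fig4_landscape, c):
        # lag offset for an exponent-p peak is (c^2/4)^(1/p): c/2 for the
        # quadratic, sqrt(c/2) for the quartic
        opts = pk.lagged_optima(fig4_landscape, c)
        peaks = pk.global_maxima(fig4_landscape)
        for opt, peak, p in zip(opts, peaks, (4, 2)):
            offset = (c * c / 4.0) ** (1.0 / p)
            assert abs(opt.location - peak.location) == pytest.approx(
                offset, abs=1e-6)
            assert abs(opt.location - peak.location) < 1.1 * max(offset, c)

    def test_root_residual_and_slope_sign(self, fig4_landscape):
        c = 1.0
        a_m = pk.global_maxima(fig4_landscape)[0].value
        for opt in pk.lagged_optima(fig4_landscape, c):
            resid = float(fig4_landscape.frozen(opt.location)) - (a_m - c * c / 4)
            assert abs(resid) < 1e-8
            h = 1e-6
            slope = (fig4_landscape.frozen(opt.location + h)
                     - fig4_landscape.frozen(opt.location - h)) / (2 * h)
            assert slope > 0

    def test_negative_speed_mirrors(self, single_peak):
        (opt,) = pk.lagged_optima(single_peak, -1.0)
        assert opt.location == pytest.approx(40.5, abs=1e-9)

    def test_empty_when_level_below_floor(self, single_peak):
        assert pk.lagged_optima(single_peak, 4.0) == []

    def test_component_lagged_optimum(self):
        comp = pk.make_bump(48.0, 2.5, 2, 2.5)
        assert ls.component_lagged_optimum(comp, 2.5) == pytest.approx(46.75)
        assert ls.component_lagged_optimum(comp, -2.5) == pytest.approx(49.25)


class TestInitialCondition:
    def test_envelope_holds_on_grid(self):
        ic = ls.gaussian_initial_condition()
        x = np.linspace(0.0, 80.0, 5001)
        assert ic.check_envelope(x)

    def test_fig4_values(self):
        ic = ls.gaussian_initial_condition()
        assert ic(37.5) == pytest.approx(0.1)
        assert ic(47.5) == pytest.approx(0.1 * math.exp(-1.0))

    def test_bad_constants_rejected(self):
        with pytest.raises(ls.ParameterError):
            ls.InitialCondition(lambda x: x, c1=-1.0, c2=1.0)


class TestPresets:
    def test_unknown_preset_lists_names(self):
        with pytest.raises(ls.ParameterError, match="fig4"):
            pk.preset("fig99")

    def test_fig6_override(self):
        ps = pk.preset("fig6", c2=1.5)
        assert ps["c_pair"] == (-1.0, 1.5)
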