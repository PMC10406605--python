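"""Arrhenius response, pooled estimator, flux filter and Q10 conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resptemp as rt
from resptemp.arrhenius import FilteredRespiration
from resptemp.exceptions import DomainError, ParameterError, SingularFitError


def _field(values):
    values = np.asarray(values, float)
    if values.ndim < 3:
        values = values.reshape(values.shape[0], 1, -1)
    return rt.gridded_field(values, lat=np.arange(values.shape[1]),
                            lon=np.arange(values.shape[2]), units="umol m-2 s-1")


class TestRespiration:
    def test_at_reference_temperature_returns_baseline(self):
        assert rt.respiration(rt.ArrheniusParams(0.65, 1.0), 283.15) == pytest.approx(1.0, abs=1e-15)

    def test_zero_activation_energy_is_temperature_independent(self):
        p = rt.ArrheniusParams(0.0, 2.5)
        t = np.array([250.0, 283.15, 310.0])
        assert np.allclose(rt.respiration(p, t), 2.5)

    def test_direct_arithmetic_value(self):
        # exp(0.5 * (1/283.15 - 1/293.15) / kB), computed independently
        assert rt.respiration(rt.ArrheniusParams(0.5, 1.0), 293.15) == pytest.approx(
            2.0117835938383446, rel=1e-12
        )

    def test_strictly_increasing_in_temperature_for_positive_ea(self):
        p = rt.ArrheniusParams(0.4, 1.7)
        t = np.linspace(255.0, 305.0, 50)
        assert np.all(np.diff(rt.respiration(p, t)) > 0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(DomainError):
            rt.respiration(rt.ArrheniusParams(0.5, 1.0), -1.0)

    def test_fixed_constants_enforced(self):
        with pytest.raises(ParameterError):
            rt.ArrheniusParams(0.5, 1.0, t_ref=273.15)
        with pytest.raises(ParameterError):
            rt.ArrheniusParams(0.5, 0.0)


class TestFilter:
    def test_negative_and_near_zero_values_masked(self):
        out = rt.filter_respiration(_field([[-0.5, 0.0, 0.005, 1.2]]), eps=0.01)
        assert out.n_retained == 1
        assert out.n_filtered == 3
        kept = out.field.values[np.isfinite(out.field.values)]
        assert kept.tolist() == [1.2]

    def test_all_positive_field_unchanged_at_zero_eps(self):
        f = _field([[0.3, 1.0, 2.0]])
        out = rt.filter_respiration(f, eps=0.0)
        assert out.n_filtered == 0
        np.testing.assert_array_equal(out.field.values, f.values)

    def test_matches_elementwise_scan(self, rng):
        vals = rng.normal(0.5, 1.0, size=(6, 4, 5))
        out = rt.filter_respiration(_field(vals), eps=0.01)
        expect_drop = vals <= 0.01
        assert out.n_filtered == expect_drop.sum()
        assert np.isnan(out.field.values[expect_drop]).all()
        np.testing.assert_array_equal(out.field.values[~expect_drop], vals[~expect_drop])

    def test_empty_result_flagged_not_raised(self):
        out = rt.filter_respiration(_field([[-1.0, -2.0]]), eps=0.01)
        assert isinstance(out, FilteredRespiration)
        assert out.all_filtered


class TestFitArrhenius:
    def test_exact_recovery_on_noiseless_grid(self, rng):
        t = rt.gridded_field(rng.uniform(260, 300, (12, 5, 6)), np.arange(5), np.arange(6), "K")
        re = t.copy(data=rt.respiration(rt.ArrheniusParams(0.50, 2.0), t.values))
        fit = rt.fit_arrhenius(re, t)
        assert fit.params.ea == pytest.approx(0.50, abs=1e-9)
        assert fit.params.re_ref == pytest.approx(2.0, abs=1e-9)
        assert fit.r2_fit == pytest.approx(1.0, abs=1e-12)

    def test_two_point_closed_form(self):
        # duplicated pairs so the n >= 3 precondition holds; the line still
        # passes exactly through both distinct (T, RE) points
        t = rt.gridded_field([[[283.15, 293.15, 283.15, 293.15]]], [45.5], np.arange(4), "K")
        re = rt.gridded_field([[[1.0, 2.0, 1.0, 2.0]]], [45.5], np.arange(4), "umol m-2 s-1")
        fit = rt.fit_arrhenius(re, t)
        assert fit.params.ea == pytest.approx(0.4957980501512411, rel=1e-12)
        assert fit.params.re_ref == pytest.approx(1.0, rel=1e-12)

    def test_recovery_under_lognormal_noise(self):
        rng = np.random.default_rng(7)
        t = rt.gridded_field(rng.uniform(260, 300, (10, 20, 50)), np.arange(20), np.arange(50), "K")
        clean = rt.respiration(rt.ArrheniusParams(0.55, 1.8), t.values)
        re = t.copy(data=clean * np.exp(rng.normal(0.0, 0.1, t.shape)))
        fit = rt.fit_arrhenius(re, t)
        assert fit.params.ea == pytest.approx(0.55, abs=0.02)

    def test_degenerate_temperatures_raise(self):
        t = rt.gridded_field(np.full((3, 1, 2), 283.15), [45.5], np.arange(2), "K")
        re = t.copy(data=np.full((3, 1, 2), 1.5))
        with pytest.raises(SingularFitError):
            rt.fit_arrhenius(re, t)

    def test_permutation_invariance(self, rng):
        t_vals = rng.uniform(260, 300, (8, 3, 4))
        re_vals = rt.respiration(rt.ArrheniusParams(0.42, 1.3), t_vals) \
            * np.exp(rng.normal(0, 0.05, t_vals.shape))
        perm = rng.permutation(t_vals.size)
        fit1 = rt.fit_arrhenius(
            rt.gridded_field(re_vals, np.arange(3), np.arange(4), "f"),
            rt.gridded_field(t_vals, np.arange(3), np.arange(4), "K"))
        fit2 = rt.fit_arrhenius(
            rt.gridded_field(re_vals.ravel()[perm].reshape(t_vals.shape), np.arange(3), np.arange(4), "f"),
            rt.gridded_field(t_vals.ravel()[perm].reshape(t_vals.shape), np.arange(3), np.arange(4), "K"))
        assert fit1.params.ea == pytest.approx(fit2.params.ea, abs=1e-9)
        assert fit1.params.re_ref == pytest.approx(fit2.params.re_ref, abs=1e-9)

    @given(c=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=25)
    def test_scaling_respiration_scales_baseline_only(self, c):
        rng = np.random.default_rng(3)
        t_vals = rng.uniform(260, 300, (6, 2, 3))
        re_vals = rt.respiration(rt.ArrheniusParams(0.5, 2.0), t_vals) \
            * np.exp(rng.normal(0, 0.1, t_vals.shape))
        t = rt.gridded_field(t_vals, np.arange(2), np.arange(3), "K")
        f1 = rt.fit_arrhenius(rt.gridded_field(re_vals, np.arange(2), np.arange(3), "f"), t)
        f2 = rt.fit_arrhenius(rt.gridded_field(c * re_vals, np.arange(2), np.arange(3), "f"), t)
        assert f2.params.ea == pytest.approx(f1.params.ea, abs=1e-9)
        assert f2.params.re_ref == pytest.approx(c * f1.params.re_ref, rel=1e-9)

    def test_filter_bookkeeping_inside_fit(self):
        t = rt.gridded_field([[[270.0, 280.0, 290.0, 300.0]]], [45.5], np.arange(4), "K")
        re = rt.gridded_field([[[-0.1, 0.9, 1.4, 2.2]]], [45.5], np.arange(4), "umol m-2 s-1")
        fit = rt.fit_arrhenius(re, t, eps=0.01)
        assert fit.n_used == 3
        assert fit.n_filtered == 1
        assert fit.n_used + fit.n_filtered == 4


class TestQ10:
    @pytest.mark.parametrize("ea, printed", [(0.65, 2.6), (0.43, 1.9), (0.38, 1.7),
                                             (0.50, 2.1), (0.53, 2.2)])
    def test_reported_equivalences_at_ten_degrees(self, ea, printed):
        assert rt.ea_to_q10(ea).rounded == printed

    def test_zero_activation_energy_gives_unity(self):
        assert rt.ea_to_q10(0.0, 291.0).q10 == 1.0

    @given(ea=st.floats(0.0, 2.0), t=st.floats(250.0, 310.0))
    @settings(deadline=None, max_examples=50)
    def test_round_trip(self, ea, t):
        assert rt.q10_to_ea(rt.ea_to_q10(ea, t).q10, t) == pytest.approx(ea, abs=1e-12)

    def test_monotone_in_ea_and_temperature(self):
        eas = np.linspace(0.0, 1.5, 20)
        q_by_ea = [rt.ea_to_q10(e, 283.15).q10 for e in eas]
        assert np.all(np.diff(q_by_ea) > 0)
        ts = np.linspace(255.0, 310.0, 20)
        q_by_t = [rt.ea_to_q10(0.5, t).q10 for t in ts]
        assert np.all(np.diff(q_by_t) < 0)
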