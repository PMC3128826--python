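"""Closed-form one-compartment relations and their structural identities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from opioidpk import (
    DoseEvent,
    NotApplicableError,
    OpioidPKParams,
    Patient,
    TherapeuticWindow,
    ValidationError,
    accumulation_ratio,
    conc_at_time,
    dose_rate,
    infusion_rate,
    loading_dose,
    oral_bolus_approx_ok,
    simulate_interval,
    steady_state_summary,
    target_css,
    tau_max,
    two_compartment_alias,
)

from conftest import superposition_peak_trough, superposition_time_average

windows = st.tuples(st.floats(0.5, 50.0), st.floats(1.05, 40.0)).map(
    lambda t: TherapeuticWindow(t[0], t[0] * t[1])
)
rates = st.floats(0.02, 2.0)
taus = st.floats(0.5, 24.0)


def _drug(k_e, v_d, cl=None, t_half=None, **kw):
    return OpioidPKParams(
        "synthetic", t_half=t_half or math.log(2) / k_e, k_e=k_e,
        v_d_per_kg=v_d, cl_per_kg=cl if cl is not None else k_e * v_d, **kw
    )


class TestTargetCss:
    def test_morphine_window_log_mean(self):
        assert round(target_css(TherapeuticWindow(10, 80)), 1) == 33.7

    def test_unit_ratio_example(self):
        assert target_css(TherapeuticWindow(1, math.e)) == pytest.approx(math.e - 1)

    def test_narrow_window_limit(self):
        c = 30.0
        assert target_css(TherapeuticWindow(c, c * (1 + 1e-9))) == pytest.approx(c)

    @given(windows)
    def test_between_geometric_and_arithmetic_mean(self, w):
        v = target_css(w)
        assert math.sqrt(w.c_min * w.c_max) < v < 0.5 * (w.c_min + w.c_max)


class TestDoseRateAndIntervals:
    @pytest.mark.parametrize(
        "css,cl,f,expected",
        [(33.7, 123.8, 1.0, 4172.06), (40, 195.9, 0.4, 19590.0), (0, 50.0, 0.5, 0.0)],
    )
    def test_dose_rate(self, css, cl, f, expected):
        assert dose_rate(css, cl, f) == pytest.approx(expected, rel=1e-4)

    def test_dose_rate_rejects_zero_bioavailability(self):
        with pytest.raises(ValidationError):
            dose_rate(30, 100, 0.0)

    def test_morphine_tau_max(self):
        assert round(tau_max(80, 10, 0.318), 1) == 6.5

    def test_halving_window_gives_one_half_life(self):
        assert tau_max(40, 20, 0.2) == pytest.approx(math.log(2) / 0.2)
        assert tau_max(80, 10, 0.693) == pytest.approx(3.0, abs=0.01)

    def test_tau_max_rejects_inverted_window(self):
        with pytest.raises(ValidationError):
            tau_max(10, 80, 0.3)


class TestAccumulationRatio:
    def test_morphine_six_hourly(self):
        assert accumulation_ratio(0.318, 6) == pytest.approx(1.174, abs=5e-4)

    def test_dosing_every_half_life_doubles_burden(self):
        assert accumulation_ratio(math.log(2), 1.0) == pytest.approx(2.0)

    def test_long_interval_limit(self):
        assert accumulation_ratio(0.3, 1e4) == pytest.approx(1.0)

    @given(rates, taus)
    def test_ar_identity(self, k_e, tau):
        ar = accumulation_ratio(k_e, tau)
        assert ar >= 1.0
        assert ar * (1 - math.exp(-k_e * tau)) == pytest.approx(1.0, rel=1e-12)

    @given(st.floats(0.02, 0.8), st.floats(0.25, 6.0))
    def test_monotone_decreasing_in_tau(self, k_e, tau):
        # ranges keep AR clear of its saturated long-interval limit of 1
        assert accumulation_ratio(k_e, tau) > accumulation_ratio(k_e, tau * 1.5)


class TestSteadyStateSummary:
    def test_iv_morphine_15mg_q6h(self, morphine, male):
        """15 mg IV every 6 h in the average male: Cavg 20.2, peak/trough
        within 2.5% of the quoted 46.2/6.8 (closed-form values 45.2/6.7)."""
        s = steady_state_summary(DoseEvent(15_000, 1.0, "iv_bolus"), 6, morphine, male)
        assert round(s.css_avg, 1) == 20.2
        assert s.cmax_ss == pytest.approx(45.2, abs=0.05)
        assert s.cmin_ss == pytest.approx(6.70, abs=0.01)
        assert s.cmax_ss == pytest.approx(46.2, rel=0.025)
        assert s.cmin_ss == pytest.approx(6.8, rel=0.025)
        assert s.t_ss == pytest.approx(19.5)

    def test_oral_10mg_q8h_underperforms(self, morphine, male):
        s = steady_state_summary(DoseEvent(10_000, 0.4, "oral"), 8, morphine, male)
        assert s.css_avg == pytest.approx(4.0, abs=0.05)

    def test_trough_peak_relation_is_exact(self, morphine, male):
        s = steady_state_summary(DoseEvent(25_000, 1.0, "iv_bolus"), 6, morphine, male)
        assert s.cmin_ss == s.cmax_ss * math.exp(-morphine.k_e * 6)
        assert s.cmin_ss < s.css_avg < s.cmax_ss

    def test_infusion_route_rejected(self, morphine, male):
        with pytest.raises(ValidationError):
            steady_state_summary(DoseEvent(1000, 1.0, "infusion"), 6, morphine, male)

    @given(
        k_e=rates, v_d=st.floats(0.5, 8.0), tau=st.floats(1.0, 24.0),
        dose=st.floats(1e3, 1e5), weight=st.floats(40.0, 150.0),
    )
    def test_superposition_oracle(self, k_e, v_d, tau, dose, weight):
        """Summing shifted single-dose exponentials reproduces the
        closed-form peak and trough to 0.1%."""
        p = _drug(k_e, v_d)
        patient = Patient(weight=weight)
        s = steady_state_summary(DoseEvent(dose, 1.0, "iv_bolus"), tau, p, patient)
        peak, trough = superposition_peak_trough(dose / (v_d * weight), k_e, tau)
        assert s.cmax_ss == pytest.approx(peak, rel=1e-3)
        assert s.cmin_ss == pytest.approx(trough, rel=1e-3)

    @given(k_e=rates, v_d=st.floats(0.5, 8.0), tau=st.floats(1.0, 24.0))
    def test_time_average_equals_clearance_form(self, k_e, v_d, tau):
        """With Cl = k_e*V_d the numeric time-average of the steady-state
        interval equals F*D/(Cl*tau) to 0.1%."""
        p = _drug(k_e, v_d)  # internally consistent clearance
        patient = Patient(weight=70.0)
        dose = 20_000.0
        s = steady_state_summary(DoseEvent(dose, 1.0, "iv_bolus"), tau, p, patient)
        avg = superposition_time_average(dose / (v_d * 70.0), k_e, tau)
        assert s.css_avg == pytest.approx(avg, rel=1e-3)

    @given(scale=st.floats(0.1, 10.0))
    def test_linear_in_dose(self, morphine, male, scale):
        a = steady_state_summary(DoseEvent(10_000, 1.0, "iv_bolus"), 6, morphine, male)
        b = steady_state_summary(
            DoseEvent(10_000 * scale, 1.0, "iv_bolus"), 6, morphine, male
        )
        assert b.css_avg == pytest.approx(scale * a.css_avg)
        assert b.cmax_ss == pytest.approx(scale * a.cmax_ss)

    def test_css_avg_inverse_in_tau(self, morphine, male):
        e = DoseEvent(10_000, 1.0, "iv_bolus")
        a = steady_state_summary(e, 4, morphine, male)
        b = steady_state_summary(e, 8, morphine, male)
        assert a.css_avg == pytest.approx(2 * b.css_avg)

    def test_degenerate_inputs_rejected(self, morphine, male):
        with pytest.raises(ValidationError):
            steady_state_summary(DoseEvent(10_000, 1.0), 0.0, morphine, male)
        with pytest.raises(ValidationError):
            DoseEvent(-5.0, 1.0)


class TestConcAtTime:
    def test_one_half_life(self):
        assert conc_at_time(100, math.log(2), 1) == pytest.approx(50.0)

    def test_window_top_to_bottom_in_tau_max(self):
        t = tau_max(80, 10, 0.318)
        assert conc_at_time(80, 0.318, t) == pytest.approx(10.0, rel=1e-12)

    def test_single_dose_trough(self):
        assert conc_at_time(38.49, 0.318, 6) == pytest.approx(5.71, abs=0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            conc_at_time(50, 0.3, -1)


class TestLoadingAndInfusion:
    def test_target_concentration_starting_dose(self):
        assert loading_dose(40, 0, 616.5, 0.4) == pytest.approx(61_650)

    def test_iv_loading_average_female(self):
        assert loading_dose(25, 0, 334.8, 1.0) == pytest.approx(8_370)

    def test_no_dose_needed_at_target(self):
        assert loading_dose(30, 30, 400, 1.0) == 0.0

    def test_target_below_current_level_rejected(self):
        with pytest.raises(ValidationError):
            loading_dose(20, 30, 400, 1.0)

    def test_infusion_rate_average_female(self):
        assert infusion_rate(25, 106.4) == pytest.approx(2_660)
        assert infusion_rate(20, 50) == 1_000

    @given(c=st.floats(0.1, 200.0), cl=st.floats(1.0, 500.0))
    def test_infusion_round_trip(self, c, cl):
        assert infusion_rate(c, cl) / cl == pytest.approx(c, rel=1e-12)


class TestOralBolusApproximation:
    def test_morphine_and_methadone_qualify(self, table):
        ok, ratio = oral_bolus_approx_ok(table.lookup("morphine"))
        assert ok and ratio == pytest.approx(15.6 / 0.318)
        ok, ratio = oral_bolus_approx_ok(table.lookup("methadone"))
        assert ok and ratio == pytest.approx(20.0, rel=1e-3)

    def test_slow_absorber_fails(self):
        p = _drug(0.3, 4.0, k_a=0.6)
        ok, ratio = oral_bolus_approx_ok(p)
        assert not ok and ratio == pytest.approx(2.0)

    def test_missing_ka_not_applicable(self):
        with pytest.raises(NotApplicableError):
            oral_bolus_approx_ok(_drug(0.3, 4.0))


class TestTwoCompartmentAlias:
    def test_terminal_rate_drives_tau_max(self):
        p = two_compartment_alias(beta=0.1, v_c_per_kg=2.0)
        assert tau_max(80, 10, p.k_e) == pytest.approx(math.log(8) / 0.1)
        assert p.v_d_per_kg == 2.0

    def test_identity_overlay(self, morphine):
        p = two_compartment_alias(morphine.k_e, morphine.v_d_per_kg, base=morphine)
        assert p.k_e == morphine.k_e and p.v_d_per_kg == morphine.v_d_per_kg
        assert p.f_by_route == morphine.f_by_route

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            two_compartment_alias(0.0, 2.0)


class TestSimulateInterval:
    def test_quarter_hour_grid_over_six_hours(self, morphine, male):
        df = simulate_interval(morphine, male, DoseEvent(15_000, 1.0), 6, dt=0.25)
        assert len(df) == 25
        s = steady_state_summary(DoseEvent(15_000, 1.0), 6, morphine, male)
        assert df["concentration_ug_per_l"].iloc[0] == pytest.approx(s.cmax_ss)
        assert df["concentration_ug_per_l"].iloc[-1] == pytest.approx(s.cmin_ss)
        assert (np.diff(df["concentration_ug_per_l"]) < 0).all()

    def test_bad_step_rejected(self, morphine, male):
        with pytest.raises(ValidationError):
            simulate_interval(morphine, male, DoseEvent(15_000, 1.0), 6, dt=0.0)
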