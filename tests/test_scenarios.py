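"""Scenario application, dose metrics, CSAF arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnpbpk.core import ModelSpec, PbpkParams, TissueParams, simulate
from mnpbpk.fluxes import (BiliaryParams, DepositionParams, ExposureSchedule,
                           GutParams)
from mnpbpk.scenarios import (Scenario, apply_scenario, average_daily_auc,
                              compute_csaf, end_of_exposure_concentration,
                              get_scenario, percent_change_from_basal)


class TestApplyScenario:
    def test_hepatic_impairment_factors(self, human):
        out = apply_scenario(human, get_scenario("hepatic_impaired"))
        assert out.model["liver"].q_blood == pytest.approx(
            0.5 * human.model["liver"].q_blood)
        assert out.bile.k_bile_c == pytest.approx(0.5 * human.bile.k_bile_c)
        # freed liver flow is rebalanced into rest-of-body; q_c conserved
        assert out.model.residual_flow == pytest.approx(
            human.model.residual_flow, abs=1e-9)
        q_rest_delta = (out.model["rest_of_body"].q_blood
                        - human.model["rest_of_body"].q_blood)
        assert q_rest_delta == pytest.approx(
            0.5 * human.model["liver"].q_blood)

    def test_aged_rat_minute_volume(self, rat):
        out = apply_scenario(rat, get_scenario("aged_rat"))
        assert out.model.q_p == pytest.approx(0.75 * rat.model.q_p)

    def test_original_untouched_and_empty_identity(self, rat):
        q_before = rat.model["liver"].q_blood
        out = apply_scenario(rat, Scenario(name="noop"))
        assert rat.model["liver"].q_blood == q_before
        assert out.to_dict() == rat.to_dict()

    def test_unknown_path_rejected(self, rat):
        with pytest.raises(KeyError):
            apply_scenario(rat, Scenario(name="bad", modifiers={"tissue.spleen.q_blood": 0.5}))

    def test_negative_residual_flow_rejected(self, rat):
        big = Scenario(name="boom", modifiers={"tissue.liver.q_blood": 50.0})
        with pytest.raises(ValueError):
            apply_scenario(rat, big)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            Scenario(name="bad", modifiers={"model.q_p": 0.0})


def _absorbing_fixture():
    """Blood-only model with pulmonary absorption, for schedule metrics."""
    comps = []
    for n in ("blood", "liver", "gut_lumen", "gut_epithelium", "lung_epithelium",
              "nasal_olfactory", "nasal_respiratory", "olfactory_bulb",
              "striatum", "cerebellum", "pituitary", "bone", "kidney",
              "rest_of_body"):
        if n == "blood":
            comps.append(TissueParams(name=n, mass=100.0))
        elif n == "striatum":
            comps.append(TissueParams(name=n, mass=10.0, q_blood=5.0,
                                      k_in=2.0, k_out=1.0))
        else:
            comps.append(TissueParams(name=n, mass=1.0))
    model = ModelSpec(species="toy", compartments=comps, q_c=10.0, q_p=100.0)
    dep = DepositionParams(f_nasal_olf=0.0, f_nasal_resp=0.0, f_pulm=0.5,
                           k_olf_transport=0.0, k_epith_absorb=0.3)
    gut = GutParams(k_abs=1e-6, k_fec=0.1, K_inh=1e30)
    return PbpkParams(model=model, dep=dep, gut=gut,
                      bile=BiliaryParams(k_bile_c=0.0))


class TestDoseMetrics:
    def test_end_of_exposure_on_sawtooth(self):
        p = _absorbing_fixture()
        sched = ExposureSchedule(air_conc=1.0, hours_per_day=6,
                                 days_per_week=5, duration_days=14)
        tc = simulate(p, sched, t_end=14 * 24.0, initial="zero", n_out=2000)
        eoe = end_of_exposure_concentration(tc, "blood")
        # dense-grid oracle: last on-phase ends at day 11 (0-based), hour 6
        t_eoe = 11 * 24.0 + 6.0
        dense = float(np.interp(t_eoe, tc.times, tc.conc("blood")))
        assert eoe == pytest.approx(dense, rel=1e-12)
        # blood peaks at on-phase ends, so EOE is close to the global max
        assert eoe == pytest.approx(tc.conc("blood").max(), rel=0.15)

    def test_continuous_schedule_uses_final_time(self):
        p = _absorbing_fixture()
        sched = ExposureSchedule(air_conc=1.0, hours_per_day=24,
                                 days_per_week=7, duration_days=10)
        tc = simulate(p, sched, t_end=240.0, initial="zero", n_out=100)
        assert end_of_exposure_concentration(tc, "blood") == pytest.approx(
            tc.conc("blood")[-1])

    def test_no_exposure_rejected(self, toy):
        tc = simulate(toy.params, toy.schedule, t_end=24.0, initial="zero")
        with pytest.raises(ValueError, match="no inhalation"):
            end_of_exposure_concentration(tc, "gut_lumen")

    def test_auc_constant_profile(self):
        # constant 0.5 ug/g over 24 h -> 12 ug*h/g/day
        p = _absorbing_fixture()
        tc = simulate(p, ExposureSchedule(), t_end=24.0, initial="zero", n_out=24)
        tc.states[:, 0] = 50.0   # hold blood at 0.5 ug/g
        assert average_daily_auc(tc, "blood") == pytest.approx(12.0)

    def test_auc_linear_ramp(self):
        # 0 -> 1 ug/g over one day: trapezoid gives 12 ug*h/g/day
        p = _absorbing_fixture()
        tc = simulate(p, ExposureSchedule(), t_end=24.0, initial="zero", n_out=240)
        tc.states[:, 0] = 100.0 * tc.times / 24.0
        assert average_daily_auc(tc, "blood") == pytest.approx(12.0, rel=1e-9)

    def test_auc_window_longer_than_run_rejected(self):
        p = _absorbing_fixture()
        tc = simulate(p, ExposureSchedule(), t_end=24.0, initial="zero")
        with pytest.raises(ValueError, match="window"):
            average_daily_auc(tc, "blood", window_days=2.0)


class TestPercentChangeAndCsaf:
    @pytest.mark.parametrize("exposed,basal,expected", [
        (0.5, 0.5, 0.0),
        (0.65, 0.5, 30.0),
        (0.5045, 0.5, 0.9),
    ])
    def test_percent_change(self, exposed, basal, expected):
        assert percent_change_from_basal(exposed, basal) == pytest.approx(expected)

    def test_percent_change_zero_basal_rejected(self):
        with pytest.raises(ValueError):
            percent_change_from_basal(1.0, 0.0)

    def test_csaf_values(self):
        # the hepatobiliary-impairment ratio and the infant/adult AUC ratio
        assert compute_csaf(0.85, 0.68) == pytest.approx(1.25)
        assert compute_csaf(7.9, 9.3) == pytest.approx(0.849462, rel=1e-5)
        assert compute_csaf(3.3, 3.3) == 1.0

    def test_csaf_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            compute_csaf(1.0, 0.0)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6), st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_csaf_scale_invariance(self, a, b, c):
        assert compute_csaf(a * c, b * c) == pytest.approx(compute_csaf(a, b),
                                                           rel=1e-9)
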