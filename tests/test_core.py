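"""Core ODE machinery: RHS arithmetic, integration, conservation."""

import numpy as np
import pytest

from mnpbpk.core import (StateVector, check_mass_balance, compile_model,
                         evaluate_rhs, simulate, steady_state)
from mnpbpk.fluxes import ExposureSchedule

from conftest import rk4


def make_state(cm, **amounts):
    """Zero state with selected free/bound amounts set by compartment name."""
    st = StateVector(a_free=np.zeros(cm.n), a_bound=np.zeros(cm.n))
    for key, val in amounts.items():
        kind, name = key.split("__")
        arr = st.a_free if kind == "free" else st.a_bound
        arr[cm.index[name]] = val
    return st


class TestEvaluateRhs:
    def test_zero_state_no_exposure_gives_zero_derivatives(self, two_comp):
        cm = compile_model(two_comp)
        st = make_state(cm)
        d = evaluate_rhs(0.0, st, two_comp, ExposureSchedule())
        assert np.all(d.a_free == 0) and np.all(d.a_bound == 0)
        assert d.cum_intake == 0 and d.cum_fecal == 0

    def test_saturated_binding_releases_at_kd(self, two_comp):
        # bound pool full, no free Mn: binding law forces d(bound)/dt = -kd*bound
        cm = compile_model(two_comp)
        cap = two_comp.model["striatum"].capacity
        st = make_state(cm, bound__striatum=cap)
        d = evaluate_rhs(0.0, st, two_comp, ExposureSchedule())
        i = cm.index["striatum"]
        assert d.a_bound[i] == pytest.approx(-two_comp.model["striatum"].k_d * cap)
        assert d.a_free[i] == pytest.approx(+two_comp.model["striatum"].k_d * cap)

    def test_two_compartment_hand_arithmetic(self, two_comp):
        # hand-evaluated: C_bl=0.5, Cf=2.0, bound=30 of capacity 100
        # bind = 0.01*2.0*(100-30) - 0.001*30 = 1.37
        # d(striatum free) = 1*0.5 - 0.5*2.0 - 1.37 = -1.87
        # d(blood free)    = 0.5*2.0 - 1*0.5        = +0.5
        cm = compile_model(two_comp)
        st = make_state(cm, free__blood=50.0, free__striatum=20.0,
                        bound__striatum=30.0)
        d = evaluate_rhs(0.0, st, two_comp, ExposureSchedule())
        i, b = cm.index["striatum"], cm.index["blood"]
        assert d.a_bound[i] == pytest.approx(1.37)
        assert d.a_free[i] == pytest.approx(-1.87)
        assert d.a_free[b] == pytest.approx(0.5)
        # closed system: derivatives sum to zero exactly
        assert d.a_free.sum() + d.a_bound.sum() == pytest.approx(0.0, abs=1e-14)

    def test_negative_state_rejected(self, two_comp):
        cm = compile_model(two_comp)
        st = make_state(cm, free__blood=-1.0)
        with pytest.raises(ValueError, match="negative"):
            evaluate_rhs(0.0, st, two_comp, ExposureSchedule())


class TestSimulate:
    def test_closed_form_infusion_elimination(self, toy):
        # A(t) = (R/k)(1 - e^{-kt}); adaptive solver must match to 1e-6 rel
        tc = simulate(toy.params, toy.schedule, t_end=100.0, initial="zero",
                      n_out=100)
        expected = toy.analytic(tc.times)
        got = tc.free_amount("gut_lumen")
        assert np.allclose(got[1:], expected[1:], rtol=1e-6)
        # closed-form limit: A(10) with R=10, k=0.1 -> 100*(1-1/e) = 63.212
        a10 = float(np.interp(10.0, tc.times, got))
        assert a10 == pytest.approx(63.212, abs=5e-3)

    def test_adaptive_solver_matches_rk4_oracle(self, two_comp):
        cm = compile_model(two_comp)
        st = make_state(cm, free__blood=50.0, free__striatum=5.0,
                        bound__striatum=10.0)
        sched = ExposureSchedule()
        tc = simulate(two_comp, sched, t_end=24.0, initial=st, n_out=4)

        def rhs(t, y):
            return cm.rhs(t, y, 0.0, 0.0, False)

        y_rk4 = rk4(rhs, st.to_array(), 0.0, 24.0, dt=0.001)
        scale = np.maximum(np.abs(y_rk4), 1e-6)
        rel = np.abs(tc.states[-1] - y_rk4) / scale
        assert rel.max() < 1e-5

    def test_rejects_nonpositive_horizon(self, toy):
        with pytest.raises(ValueError):
            simulate(toy.params, toy.schedule, t_end=0.0, initial="zero")

    def test_bound_never_exceeds_capacity(self, two_comp):
        cm = compile_model(two_comp)
        st = make_state(cm, free__blood=500.0, bound__striatum=99.0)
        tc = simulate(two_comp, ExposureSchedule(), t_end=200.0, initial=st,
                      n_out=100)
        cap = two_comp.model["striatum"].capacity
        assert np.all(tc.bound_amount("striatum") <= cap + 1e-9)


class TestMassBalance:
    def test_closed_system_conserves_exactly(self, two_comp):
        cm = compile_model(two_comp)
        st = make_state(cm, free__blood=40.0, free__striatum=5.0)
        tc = simulate(two_comp, ExposureSchedule(), t_end=100.0, initial=st,
                      n_out=20)
        assert check_mass_balance(tc) < 1e-9
        assert np.allclose(tc.total_body(), 45.0, rtol=1e-8)

    def test_dietary_simulation_balances(self, rat):
        sched = rat.default_schedule(duration_days=14)
        tc = simulate(rat, sched, t_end=14 * 24.0, n_out=50)
        assert check_mass_balance(tc) < 1e-6

    def test_perturbed_course_is_flagged(self, rat):
        sched = rat.default_schedule(duration_days=14)
        tc = simulate(rat, sched, t_end=14 * 24.0, n_out=50)
        tc.states[-1, 0] += 0.05 * tc.total_body()[0]   # corrupt blood amount
        assert check_mass_balance(tc) > 1e-3


class TestSteadyState:
    def test_diet_only_steady_state_is_invariant_over_30_days(self, monkey):
        diet = monkey.default_schedule().diet_ug_per_h
        ss = steady_state(monkey, diet)
        sched = monkey.default_schedule(duration_days=30)
        tc = simulate(monkey, sched, t_end=30 * 24.0, initial=ss, n_out=30)
        for tissue in ("globus_pallidus", "liver", "blood", "bone"):
            c = tc.conc(tissue)
            assert np.all(np.abs(c - c[0]) <= 1e-4 * abs(c[0]) + 1e-12)

    def test_algebraic_and_integrated_routes_agree(self, monkey):
        # verify=True integrates forward and insists on < 0.1% drift
        diet = monkey.default_schedule().diet_ug_per_h
        steady_state(monkey, diet, verify=True)

    def test_zero_intake_gives_empty_body(self, monkey):
        ss = steady_state(monkey, 0.0)
        assert ss.total_body() == 0.0

    def test_washout_returns_brain_to_baseline(self, rat):
        # 90-day subchronic rat exposure then 60 days clean air: striatal Mn
        # must come back to within 5% of the pre-exposure level
        sched = rat.default_schedule(air_conc=0.5, hours_per_day=6,
                                     days_per_week=5, duration_days=90)
        tc = simulate(rat, sched, t_end=150 * 24.0, n_out=300)
        c = tc.conc("striatum")
        assert c.max() > 1.2 * c[0]          # the exposure actually did something
        assert abs(c[-1] - c[0]) / c[0] < 0.05

    def test_washout_is_monotone_toward_baseline(self, rat):
        sched = rat.default_schedule(air_conc=0.5, hours_per_day=6,
                                     days_per_week=5, duration_days=90)
        tc = simulate(rat, sched, t_end=150 * 24.0, n_out=600)
        free = tc.free_conc("striatum")
        tail = free[tc.times > 91 * 24.0]
        assert np.all(np.diff(tail) <= 1e-9 + 1e-6 * tail[:-1])
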