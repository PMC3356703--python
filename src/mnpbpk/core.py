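"""Compartmental PBPK core: state, ODE right-hand side, integrator.

The model tracks free and bound manganese amounts (μg) in every compartment.
Free Mn exchanges between blood and tissues by asymmetric diffusional fluxes
(``k_in`` applied to the blood concentration, ``k_out`` to the tissue free
concentration); each tissue binds free Mn to a saturable pool of capacity
``b_max * mass`` with association/dissociation constants ``k_a``/``k_d``.
Route-specific external fluxes (inhalation deposition, diet, gut absorption,
enterocyte sloughing, biliary excretion, olfactory transport) come from
:mod:`mnpbpk.fluxes`.

State variables are amounts rather than concentrations so that conservation
can be checked exactly: at all times

    total body Mn(t) + cumulative fecal(t) = total(0) + cumulative intake(t).

Exposure schedules are handled by piecewise integration with a solver restart
at every on/off transition (schedules are explicit, so no event root-finding
is needed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint
from scipy.optimize import brentq

from .fluxes import (
    BiliaryParams,
    DepositionParams,
    ExposureSchedule,
    GutParams,
)

# Compartments that every full species model must contain.  ``brain_target``
# (striatum in the rat, globus pallidus in primates) is species-specific and
# declared on the parameter set, not here.
SPECIAL_COMPARTMENTS = (
    "blood",
    "liver",
    "gut_lumen",
    "gut_epithelium",
    "lung_epithelium",
    "nasal_olfactory",
    "nasal_respiratory",
    "olfactory_bulb",
)


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails to converge."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (at t = {t_fail:.6g} h)")
        self.t_fail = t_fail


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class TissueParams:
    """Physiology and Mn kinetics of one compartment.

    mass      g (volume L = mass/1000; density 1 g/mL)
    q_blood   tissue blood flow, L/h
    k_in      diffusional influx coefficient, mL/h, applied to blood free
              concentration (μg/mL == μg/g)
    k_out     diffusional efflux coefficient, mL/h, applied to tissue free conc
    b_max     binding capacity, μg Mn per g tissue
    k_a       association rate, g·μg⁻¹·h⁻¹
    k_d       dissociation rate, h⁻¹

    Flux coefficients multiply concentrations in μg/mL, so they carry mL/h;
    blood flows stay in L/h (1 L/h = 1000 mL/h when the two meet in the
    delivery cap).
    """

    name: str
    mass: float
    q_blood: float = 0.0
    k_in: float = 0.0
    k_out: float = 0.0
    b_max: float = 0.0
    k_a: float = 0.0
    k_d: float = 0.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.name}: mass must be > 0")
        for attr in ("q_blood", "k_in", "k_out", "b_max", "k_a", "k_d"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")

    @property
    def capacity(self) -> float:
        """Total binding capacity b_max*mass, μg."""
        return self.b_max * self.mass

    @property
    def k_in_effective(self) -> float:
        """Influx coefficient capped at the blood delivery limit.

        Diffusional uptake cannot exceed what perfusion delivers:
        k_in·C_blood ≤ q_blood·C_blood, with q_blood (L/h) converted to the
        mL/h convention of k_in.
        """
        if self.q_blood > 0:
            return min(self.k_in, 1000.0 * self.q_blood)
        return self.k_in


@dataclass
class ModelSpec:
    """Ordered compartment list plus whole-body flows and route switches."""

    species: str
    compartments: list[TissueParams]
    q_c: float               # cardiac output, L/h
    q_p: float               # pulmonary ventilation, L/h
    oral: bool = True
    inhalation: bool = True

    def __post_init__(self) -> None:
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("compartment names must be unique")
        for required in SPECIAL_COMPARTMENTS:
            if required not in names:
                raise ValueError(f"model is missing required compartment {required!r}")
        if self.q_c <= 0 or self.q_p <= 0:
            raise ValueError("q_c and q_p must be > 0")
        perfused = sum(c.q_blood for c in self.compartments if c.name != "blood")
        if perfused > self.q_c * (1 + 1e-9):
            raise ValueError(
                f"tissue blood flows sum to {perfused:.4g} L/h > cardiac output {self.q_c:.4g}"
            )

    def __getitem__(self, name: str) -> TissueParams:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    @property
    def residual_flow(self) -> float:
        """Cardiac output not assigned to any named compartment."""
        return self.q_c - sum(c.q_blood for c in self.compartments if c.name != "blood")


@dataclass
class PbpkParams:
    """Bundle of everything the ODE needs: model + route-flux parameters."""

    model: ModelSpec
    dep: DepositionParams
    gut: GutParams
    bile: BiliaryParams


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


@dataclass
class StateVector:
    """Amount-based model state.

    ``a_free``/``a_bound`` are μg per compartment, in model order.  The three
    cumulative counters support exact mass-balance accounting; ``cum_bile`` is
    informational (biliary flux is internal to the body, lumen included).
    """

    a_free: np.ndarray
    a_bound: np.ndarray
    cum_intake: float = 0.0
    cum_fecal: float = 0.0
    cum_bile: float = 0.0

    def validate(self, cm: "CompiledModel", tol: float = 1e-9) -> None:
        if np.any(self.a_free < -tol) or np.any(self.a_bound < -tol):
            raise ValueError("negative state component")
        if np.any(self.a_bound > cm.capacity + tol + 1e-12 * np.abs(cm.capacity)):
            raise ValueError("bound amount exceeds binding capacity")

    def to_array(self) -> np.ndarray:
        return np.concatenate(
            [self.a_free, self.a_bound,
             [self.cum_intake, self.cum_fecal, self.cum_bile]]
        )

    @classmethod
    def from_array(cls, y: np.ndarray, n: int) -> "StateVector":
        return cls(a_free=np.asarray(y[:n], dtype=float).copy(),
                   a_bound=np.asarray(y[n:2 * n], dtype=float).copy(),
                   cum_intake=float(y[2 * n]),
                   cum_fecal=float(y[2 * n + 1]),
                   cum_bile=float(y[2 * n + 2]))

    def total_body(self) -> float:
        return float(self.a_free.sum() + self.a_bound.sum())


# ---------------------------------------------------------------------------
# Compiled model: flat arrays + fast RHS
# ---------------------------------------------------------------------------


class CompiledModel:
    """Flat-array view of a :class:`PbpkParams` for fast RHS evaluation."""

    def __init__(self, params: PbpkParams):
        model = params.model
        self.params = params
        self.names = model.names
        self.index = {n: i for i, n in enumerate(self.names)}
        n = self.n = len(self.names)

        self.mass = np.array([c.mass for c in model.compartments])
        self.kin = np.array([c.k_in_effective for c in model.compartments])
        self.kout = np.array([c.k_out for c in model.compartments])
        self.ka = np.array([c.k_a for c in model.compartments])
        self.kd = np.array([c.k_d for c in model.compartments])
        self.capacity = np.array([c.capacity for c in model.compartments])

        self.i_bl = self.index["blood"]
        self.i_liv = self.index["liver"]
        self.i_lum = self.index["gut_lumen"]
        self.i_ge = self.index["gut_epithelium"]
        self.i_lung = self.index["lung_epithelium"]
        self.i_nolf = self.index["nasal_olfactory"]
        self.i_nresp = self.index["nasal_respiratory"]
        self.i_bulb = self.index["olfactory_bulb"]

        # Blood and gut lumen never exchange by k_in/k_out with themselves.
        self.kin[self.i_bl] = 0.0
        self.kout[self.i_bl] = 0.0
        self.kin[self.i_lum] = 0.0
        self.kout[self.i_lum] = 0.0

        self.nv = 2 * n + 3  # free + bound + three cumulative counters

    # -- RHS ----------------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, diet_rate: float, air_conc: float,
            exposure_on: bool) -> np.ndarray:
        """Time derivative of the flat state vector (μg/h)."""
        p = self.params
        n = self.n
        af = y[:n]
        ab = y[n:2 * n]

        cf = af / self.mass
        c_bl = cf[self.i_bl]

        bind = self.ka * cf * (self.capacity - ab) - self.kd * ab
        influx = self.kin * c_bl
        efflux = self.kout * cf
        daf = influx - efflux - bind

        dy = np.empty(self.nv)
        dab = bind

        # blood: diffusional exchange with every tissue + respiratory absorption
        k_ab = p.dep.k_epith_absorb
        resp_absorb = k_ab * (af[self.i_lung] + af[self.i_nolf] + af[self.i_nresp])
        daf[self.i_bl] = efflux.sum() - influx.sum() + resp_absorb

        # inhalation deposition
        if exposure_on and air_conc > 0.0:
            base = air_conc * p.model.q_p
            dep_olf = base * p.dep.f_nasal_olf
            dep_resp = base * p.dep.f_nasal_resp
            dep_pulm = base * p.dep.f_pulm
        else:
            dep_olf = dep_resp = dep_pulm = 0.0

        daf[self.i_lung] += dep_pulm - k_ab * af[self.i_lung]
        daf[self.i_nresp] += dep_resp - k_ab * af[self.i_nresp]
        olf_to_bulb = p.dep.k_olf_transport * af[self.i_nolf]
        daf[self.i_nolf] += dep_olf - k_ab * af[self.i_nolf] - olf_to_bulb
        daf[self.i_bulb] += olf_to_bulb

        # gut lumen: diet + bile in; absorption + fecal out
        a_lum = af[self.i_lum]
        absorb = p.gut.k_abs * a_lum / (1.0 + (a_lum / p.gut.K_inh) ** p.gut.n_inh)
        fecal_lum = p.gut.k_fec * a_lum
        cf_liv = cf[self.i_liv]
        bile = p.bile.k_bile_c * cf_liv * p.bile.induction_factor(cf_liv)
        daf[self.i_lum] += diet_rate + bile - absorb - fecal_lum

        # gut epithelium: absorption in; portal uptake + sloughing out
        slough = p.gut.k_slough * af[self.i_ge]
        portal = p.gut.k_absorb_portal * af[self.i_ge]
        daf[self.i_ge] += absorb - portal - slough

        # liver: portal (first-pass) input, biliary output
        daf[self.i_liv] += portal - bile

        dy[:n] = daf
        dy[n:2 * n] = dab
        dy[2 * n] = diet_rate + dep_olf + dep_resp + dep_pulm   # cum intake
        dy[2 * n + 1] = fecal_lum + slough                       # cum fecal
        dy[2 * n + 2] = bile                                     # cum bile
        return dy


def compile_model(params: PbpkParams) -> CompiledModel:
    return CompiledModel(params)


def evaluate_rhs(t: float, state: StateVector, params: PbpkParams,
                 schedule: ExposureSchedule) -> StateVector:
    """Public RHS: derivative of ``state`` under ``schedule`` at time ``t``.

    Rejects states with negative components.  The returned object holds
    derivative values (μg/h) in the same layout as the state.
    """
    cm = compile_model(params)
    state.validate(cm)
    y = state.to_array()
    dy = cm.rhs(t, y, schedule.diet_ug_per_h, schedule.air_conc,
                schedule.exposure_on(t))
    return StateVector.from_array(dy, cm.n)


# ---------------------------------------------------------------------------
# Time course container
# ---------------------------------------------------------------------------


@dataclass
class TimeCourse:
    """Simulation output on a time grid.

    ``states`` is the raw (n_times, n_state) array; concentrations are
    derived on demand so they are consistent with the states to machine
    precision.
    """

    times: np.ndarray
    states: np.ndarray
    compiled: CompiledModel
    schedule: ExposureSchedule

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    # -- accessors ----------------------------------------------------------

    def _idx(self, tissue: str) -> int:
        try:
            return self.compiled.index[tissue]
        except KeyError:
            raise KeyError(
                f"unknown compartment {tissue!r}; have {self.compiled.names}")

    def free_amount(self, tissue: str) -> np.ndarray:
        return self.states[:, self._idx(tissue)]

    def bound_amount(self, tissue: str) -> np.ndarray:
        return self.states[:, self.compiled.n + self._idx(tissue)]

    def conc(self, tissue: str) -> np.ndarray:
        """Total (free + bound) concentration, μg/g."""
        i = self._idx(tissue)
        return (self.states[:, i] + self.states[:, self.compiled.n + i]) / self.compiled.mass[i]

    def free_conc(self, tissue: str) -> np.ndarray:
        i = self._idx(tissue)
        return self.states[:, i] / self.compiled.mass[i]

    @property
    def cum_intake(self) -> np.ndarray:
        return self.states[:, 2 * self.compiled.n]

    @property
    def cum_fecal(self) -> np.ndarray:
        return self.states[:, 2 * self.compiled.n + 1]

    @property
    def cum_bile(self) -> np.ndarray:
        return self.states[:, 2 * self.compiled.n + 2]

    def total_body(self) -> np.ndarray:
        n = self.compiled.n
        return self.states[:, :2 * n].sum(axis=1)

    def exposure_flags(self) -> np.ndarray:
        """True where inhalation is active just before each grid time."""
        return np.array([self.schedule.exposure_on(t - 1e-9) for t in self.times])

    def state_at(self, t: float) -> StateVector:
        j = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[j] - t) > 1e-6 * max(1.0, abs(t)):
            raise KeyError(f"time {t} not on the output grid")
        return StateVector.from_array(self.states[j], self.compiled.n)

    # -- export -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_h, compartment, free_ug, bound_ug, conc, flag."""
        n = self.compiled.n
        flags = self.exposure_flags()
        rows = []
        for i, name in enumerate(self.compiled.names):
            rows.append(pd.DataFrame({
                "time_h": self.times,
                "compartment": name,
                "free_ug": self.states[:, i],
                "bound_ug": self.states[:, n + i],
                "conc_ug_per_g": (self.states[:, i] + self.states[:, n + i]) / self.compiled.mass[i],
                "exposure_on": flags,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive stiff-integrator (LSODA) settings."""

    rtol: float = 1e-8
    atol: float = 1e-10   # μg
    mxstep: int = 500_000


def _dedupe_times(t: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Drop grid points closer than ``eps`` hours to their predecessor."""
    t = np.unique(t)
    if t.size < 2:
        return t
    keep = np.concatenate([[True], np.diff(t) > eps])
    return t[keep]


def _segment_grid(t0: float, t1: float, t_eval: np.ndarray) -> np.ndarray:
    inner = t_eval[(t_eval > t0 + 1e-7) & (t_eval < t1 - 1e-7)]
    return np.concatenate([[t0], inner, [t1]])


def simulate(params: PbpkParams, schedule: ExposureSchedule,
             t_end: Optional[float] = None,
             solver: SolverSettings = SolverSettings(),
             t_eval: Optional[Sequence[float]] = None,
             initial: "str | StateVector" = "steady_state",
             n_out: int = 400) -> TimeCourse:
    """Integrate the model across an intermittent exposure schedule.

    ``initial`` may be a :class:`StateVector`, ``"steady_state"`` (diet-only
    steady state of the schedule's dietary rate) or ``"zero"``.  The output
    grid is the union of ``t_eval`` (default ``n_out`` uniform points) and
    every exposure on/off transition, so end-of-exposure values are exact
    grid points.
    """
    if t_end is None:
        t_end = schedule.duration_days * 24.0
    if t_end <= 0:
        raise ValueError("t_end must be > 0")

    cm = compile_model(params)
    if isinstance(initial, StateVector):
        initial.validate(cm)
        y0 = initial.to_array()
    elif initial == "steady_state":
        y0 = steady_state(params, schedule.diet_ug_per_h).to_array()
    elif initial == "zero":
        y0 = np.zeros(cm.nv)
    else:
        raise ValueError(f"unknown initial condition {initial!r}")

    if t_eval is None:
        grid = np.linspace(0.0, t_end, n_out + 1)
    else:
        grid = np.asarray(t_eval, dtype=float)
        if grid.ndim != 1 or np.any(grid < 0) or np.any(grid > t_end * (1 + 1e-12)):
            raise ValueError("t_eval must lie within [0, t_end]")

    # breakpoints: all exposure transitions within (0, t_end)
    breaks = [0.0]
    for a, b in schedule.on_windows(t_end):
        breaks += [a, b]
    breaks.append(t_end)
    breaks = _dedupe_times(np.clip(np.array(breaks), 0.0, t_end))

    # breaks take precedence over nearby requested points so that every
    # segment boundary is exactly on the output grid
    grid = grid[np.min(np.abs(grid[:, None] - breaks[None, :]), axis=1) > 1e-7]
    grid = np.unique(np.concatenate([grid, breaks]))

    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    diet = schedule.diet_ug_per_h
    y = y0.copy()
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        on = schedule.exposure_on(0.5 * (t0 + t1))
        ts = _segment_grid(t0, t1, grid)

        def f(yv, tv, _on=on):
            return cm.rhs(tv, yv, diet, schedule.air_conc, _on)

        sol, info = odeint(f, y, ts, rtol=solver.rtol, atol=solver.atol,
                           mxstep=solver.mxstep, full_output=True)
        if info["message"] != "Integration successful.":
            raise SolverError(info["message"], t_fail=float(info["tcur"][-1]))
        y = sol[-1]
        keep = np.isin(ts, grid)
        if out_t:  # avoid duplicating the segment start
            keep[0] = False
        out_t.append(ts[keep])
        out_y.append(sol[keep])

    times = np.concatenate(out_t)
    states = np.concatenate(out_y, axis=0)
    return TimeCourse(times=times, states=states, compiled=cm, schedule=schedule)


# ---------------------------------------------------------------------------
# Mass balance
# ---------------------------------------------------------------------------


def check_mass_balance(tc: TimeCourse) -> float:
    """Maximum relative conservation residual over the output grid.

    residual(t) = |body(t) + fecal(t) - body(0) - intake(t)|
                  / max(body(0), intake(t))
    """
    body = tc.total_body()
    intake = tc.cum_intake
    fecal = tc.cum_fecal
    if tc.states.shape[1] != 2 * tc.compiled.n + 3:
        raise ValueError("time course lacks cumulative counters")
    denom = np.maximum(body[0], np.maximum(intake, 1e-300))
    resid = np.abs(body + fecal - body[0] - intake) / denom
    return float(resid.max())


# ---------------------------------------------------------------------------
# Diet-only steady state (algebraic cascade + optional verification run)
# ---------------------------------------------------------------------------


def steady_state(params: PbpkParams, diet_ug_per_h: float,
                 air_conc: float = 0.0, verify: bool = False,
                 verify_hours: float = 500.0, verify_tol: float = 1e-3) -> StateVector:
    """Steady state under continuous diet (and optional continuous inhalation).

    Solved algebraically by a nested-bracketing cascade: for a trial blood
    free concentration the liver/bile/lumen/epithelium subsystem is resolved
    (biliary recirculation included), and the whole-body balance
    ``fecal output = diet + deposited inhalation`` is closed by a 1-D root
    solve on the blood concentration.  The cascade assumes the gut lumen,
    gut epithelium and respiratory epithelia have no diffusional k_in/k_out
    exchange of their own (true of all shipped parameter sets).

    With ``verify=True`` the state is additionally integrated forward and the
    relative drift of every compartment is required to stay below
    ``verify_tol`` (default 0.1%).
    """
    cm = compile_model(params)
    p = params
    for i in (cm.i_lum, cm.i_ge, cm.i_lung, cm.i_nolf, cm.i_nresp):
        if cm.kin[i] != 0.0 or cm.kout[i] != 0.0:
            raise ValueError(
                "steady_state cascade requires zero k_in/k_out on lumen and epithelia")

    if diet_ug_per_h == 0.0 and air_conc == 0.0:
        return StateVector(a_free=np.zeros(cm.n), a_bound=np.zeros(cm.n))

    dep_olf = air_conc * p.model.q_p * p.dep.f_nasal_olf
    dep_resp = air_conc * p.model.q_p * p.dep.f_nasal_resp
    dep_pulm = air_conc * p.model.q_p * p.dep.f_pulm
    dep_total = dep_olf + dep_resp + dep_pulm

    k_ab = p.dep.k_epith_absorb
    gut = p.gut
    bile_p = p.bile
    kin_liv = cm.kin[cm.i_liv]
    kout_liv = cm.kout[cm.i_liv]
    mass_liv = cm.mass[cm.i_liv]

    def lumen_amount(total_in: float) -> float:
        """Lumen amount solving in = absorption + fecal (monotone)."""
        if total_in == 0.0:
            return 0.0

        def g(a):
            return (gut.k_abs * a / (1.0 + (a / gut.K_inh) ** gut.n_inh)
                    + gut.k_fec * a - total_in)

        hi = total_in / gut.k_fec * 1.001 + 1.0
        while g(hi) < 0:
            hi *= 4.0
        return brentq(g, 0.0, hi, xtol=1e-14, rtol=1e-14)

    def gut_state(bile_flux: float):
        a_lum = lumen_amount(diet_ug_per_h + bile_flux)
        absorb = gut.k_abs * a_lum / (1.0 + (a_lum / gut.K_inh) ** gut.n_inh)
        denom = gut.k_absorb_portal + gut.k_slough
        a_ge = absorb / denom if denom > 0 else 0.0
        portal = gut.k_absorb_portal * a_ge
        return a_lum, a_ge, portal

    def liver_cf(c_bl: float, portal: float) -> float:
        """Liver free conc solving influx + portal = efflux + bile."""
        inflow = kin_liv * c_bl + portal
        if inflow == 0.0:
            return 0.0

        def g(cf):
            return (kout_liv * cf
                    + bile_p.k_bile_c * cf * bile_p.induction_factor(cf) - inflow)

        hi = inflow / max(kout_liv + bile_p.k_bile_c, 1e-12) * 1.001 + 1e-9
        while g(hi) < 0:
            hi *= 4.0
        return brentq(g, 0.0, hi, xtol=1e-16, rtol=1e-14)

    def bile_fixed_point(c_bl: float) -> tuple[float, float, float, float]:
        """Resolve biliary recirculation at fixed blood concentration."""
        def g(b):
            _, _, portal = gut_state(b)
            cf = liver_cf(c_bl, portal)
            return bile_p.k_bile_c * cf * bile_p.induction_factor(cf) - b

        hi = 1.0
        while g(hi) > 0:
            hi *= 4.0
            if hi > 1e12:
                raise RuntimeError("biliary recirculation fixed point diverged")
        b = brentq(g, 0.0, hi, xtol=1e-14, rtol=1e-14)
        a_lum, a_ge, portal = gut_state(b)
        return b, a_lum, a_ge, portal

    def balance(c_bl: float) -> float:
        _, a_lum, a_ge, _ = bile_fixed_point(c_bl)
        fecal = gut.k_fec * a_lum + gut.k_slough * a_ge
        return fecal - diet_ug_per_h - dep_total

    lo, hi = 0.0, 1e-3
    while balance(hi) < 0:
        hi *= 4.0
        if hi > 1e9:
            raise RuntimeError("steady-state blood concentration bracket diverged")
    c_bl = brentq(balance, lo, hi, xtol=1e-18, rtol=1e-13)

    bile_flux, a_lum, a_ge, portal = bile_fixed_point(c_bl)
    cf = np.zeros(cm.n)
    cf[cm.i_bl] = c_bl
    for i in range(cm.n):
        if i in (cm.i_bl, cm.i_lum, cm.i_ge, cm.i_lung, cm.i_nolf, cm.i_nresp,
                 cm.i_liv, cm.i_bulb):
            continue
        if cm.kout[i] > 0:
            cf[i] = cm.kin[i] * c_bl / cm.kout[i]
        elif cm.kin[i] > 0:
            raise RuntimeError(f"compartment {cm.names[i]} has influx but no efflux")
    cf[cm.i_liv] = liver_cf(c_bl, portal)

    a_free = cf * cm.mass
    a_free[cm.i_lum] = a_lum
    a_free[cm.i_ge] = a_ge
    a_free[cm.i_lung] = dep_pulm / k_ab if k_ab > 0 else 0.0
    a_free[cm.i_nresp] = dep_resp / k_ab if k_ab > 0 else 0.0
    olf_denom = k_ab + p.dep.k_olf_transport
    a_free[cm.i_nolf] = dep_olf / olf_denom if olf_denom > 0 else 0.0
    # olfactory bulb: diffusional input plus direct olfactory transport
    olf_in = p.dep.k_olf_transport * a_free[cm.i_nolf]
    if cm.kout[cm.i_bulb] > 0:
        cf[cm.i_bulb] = (cm.kin[cm.i_bulb] * c_bl + olf_in) / cm.kout[cm.i_bulb]
        a_free[cm.i_bulb] = cf[cm.i_bulb] * cm.mass[cm.i_bulb]

    with np.errstate(invalid="ignore", divide="ignore"):
        occ = cm.ka * cf / np.where(cm.ka * cf + cm.kd > 0, cm.ka * cf + cm.kd, 1.0)
    a_bound = cm.capacity * occ

    state = StateVector(a_free=a_free, a_bound=a_bound)

    if verify:
        sched = ExposureSchedule(air_conc=air_conc, hours_per_day=24.0,
                                 days_per_week=7,
                                 duration_days=verify_hours / 24.0 + 1,
                                 diet_rate=diet_ug_per_h * 24.0 / 1000.0)
        tc = simulate(params, sched, t_end=verify_hours, initial=state, n_out=10)
        ref = np.maximum(np.abs(state.to_array()[:2 * cm.n]), 1e-9)
        drift = np.abs(tc.states[-1, :2 * cm.n] - state.to_array()[:2 * cm.n]) / ref
        if drift.max() > verify_tol:
            raise RuntimeError(
                f"steady-state verification drift {drift.max():.3g} exceeds {verify_tol}")
    return state
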