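"""Synthetic data: closed-form fixtures, noisy observations, canned schedules.

Nothing here is measured data.  The module generates every input the test
suite and the calibration-recovery studies need: a one-compartment fixture
with an analytic solution that serves as an independent solver oracle, noisy
tissue "observations" produced from a known parameter set (so downstream
code can compute exact recovery error), and the exposure designs used by the
shipped scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ModelSpec, PbpkParams, TissueParams, simulate
from .fluxes import BiliaryParams, DepositionParams, ExposureSchedule, GutParams


# ---------------------------------------------------------------------------
# Closed-form fixtures
# ---------------------------------------------------------------------------


@dataclass
class ToyFixture:
    """Constant-infusion / first-order-loss system with analytic solution.

    The fixture is embedded in a full model: dietary input R (μg/h) enters
    the gut lumen, whose only exit is first-order fecal loss k (1/h); every
    other exchange is switched off.  The lumen amount then follows
    ``A(t) = (R/k)(1 - exp(-k t))`` exactly, independent of the rest of the
    system, which lets the full integrator be checked against a closed form.
    """

    params: PbpkParams
    schedule: ExposureSchedule
    infusion_rate: float   # μg/h
    loss_rate: float       # 1/h
    compartment: str = "gut_lumen"

    def analytic(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.infusion_rate / self.loss_rate) * (1.0 - np.exp(-self.loss_rate * t))


def _inert_tissue(name: str, mass: float = 1.0) -> TissueParams:
    return TissueParams(name=name, mass=mass, q_blood=0.0)


def make_toy_fixture(infusion_rate: float = 10.0, loss_rate: float = 0.1) -> ToyFixture:
    """One-compartment infusion–elimination fixture (defaults R=10 μg/h, k=0.1/h)."""
    comps = [_inert_tissue(n) for n in
             ("blood", "liver", "gut_lumen", "gut_epithelium", "lung_epithelium",
              "nasal_olfactory", "nasal_respiratory", "olfactory_bulb",
              "striatum", "cerebellum", "pituitary", "bone", "kidney",
              "rest_of_body")]
    model = ModelSpec(species="toy", compartments=comps, q_c=1.0, q_p=1.0)
    dep = DepositionParams(f_nasal_olf=0.0, f_nasal_resp=0.0, f_pulm=0.0,
                           k_olf_transport=0.0, k_epith_absorb=0.0)
    # k_abs tiny but positive (the basal absorbed fraction must be in (0,1));
    # its contribution to the lumen exit rate is folded into the analytic k.
    eps = loss_rate * 1e-12
    gut = GutParams(k_abs=eps, k_fec=loss_rate - eps, K_inh=1e30,
                    k_slough=1.0, k_absorb_portal=0.0)
    bile = BiliaryParams(k_bile_c=0.0)
    params = PbpkParams(model=model, dep=dep, gut=gut, bile=bile)
    schedule = ExposureSchedule(diet_rate=infusion_rate * 24.0 / 1000.0)
    return ToyFixture(params=params, schedule=schedule,
                      infusion_rate=infusion_rate, loss_rate=loss_rate)


def make_two_compartment_fixture() -> PbpkParams:
    """Blood plus one binding tissue with simple hand-checkable constants.

    striatum: k_in 1, k_out 0.5 (mL/h, applied to μg/mL), k_a 0.01,
    k_d 0.001, capacity b_max·mass = 100 μg (mass 10 g); everything else
    inert.
    """
    comps = []
    for n in ("blood", "liver", "gut_lumen", "gut_epithelium", "lung_epithelium",
              "nasal_olfactory", "nasal_respiratory", "olfactory_bulb",
              "striatum", "cerebellum", "pituitary", "bone", "kidney",
              "rest_of_body"):
        if n == "blood":
            comps.append(TissueParams(name=n, mass=100.0))
        elif n == "striatum":
            comps.append(TissueParams(name=n, mass=10.0, q_blood=10.0,
                                      k_in=1.0, k_out=0.5, b_max=10.0,
                                      k_a=0.01, k_d=0.001))
        else:
            comps.append(_inert_tissue(n))
    model = ModelSpec(species="toy2", compartments=comps, q_c=20.0, q_p=1.0)
    dep = DepositionParams(f_nasal_olf=0.0, f_nasal_resp=0.0, f_pulm=0.0,
                           k_olf_transport=0.0, k_epith_absorb=0.0)
    gut = GutParams(k_abs=1e-6, k_fec=0.1, K_inh=1e30)
    bile = BiliaryParams(k_bile_c=0.0)
    return PbpkParams(model=model, dep=dep, gut=gut, bile=bile)


# ---------------------------------------------------------------------------
# Noisy synthetic observations
# ---------------------------------------------------------------------------


def generate_synthetic_observations(params, schedule: ExposureSchedule,
                                    tissues: Sequence[str],
                                    times: Sequence[float],
                                    noise_cv: float, seed: int,
                                    ) -> pd.DataFrame:
    """Noisy tissue concentrations with the generating truth attached.

    observed = true · exp(ε), ε ~ N(0, σ²) with σ² = ln(1 + cv²), so the
    observation CV equals ``noise_cv`` and observations stay positive.  Note
    E[observed | true] = true·exp(σ²/2), i.e. the noise is multiplicative and
    mean-biased upward by that factor; recovery studies fit in log space
    where the noise is unbiased.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    times = sorted(float(t) for t in times)   # replicate times allowed
    unique = sorted(set(times))
    t_end = max(max(times), schedule.duration_days * 24.0, 1.0)
    tc = simulate(params, schedule, t_end=t_end,
                  t_eval=[0.0] + unique + [t_end], n_out=0)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
    rows = []
    for tissue in tissues:
        conc = tc.conc(tissue)
        for t in times:
            true = float(np.interp(t, tc.times, conc))
            eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            rows.append({"time_h": t, "tissue": tissue,
                         "observed": true * math.exp(eps), "true": true,
                         "noise_cv": noise_cv, "seed": seed})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Canned exposure designs
# ---------------------------------------------------------------------------


def canned_schedules() -> dict[str, ExposureSchedule]:
    """The exposure designs used by the shipped scenario simulations.

    Diet is left unset; fill it per species with
    ``dataclasses.replace(sched, **params.default_diet)`` or build via
    :meth:`SpeciesParameterSet.default_schedule`.
    """
    return {
        # occupational pattern at the ACGIH TLV, one year
        "occupational_human": ExposureSchedule(
            air_conc=0.2, hours_per_day=8.0, days_per_week=5, duration_days=365),
        # subchronic monkey inhalation design
        "monkey_subchronic": ExposureSchedule(
            air_conc=0.2, hours_per_day=6.0, days_per_week=5, duration_days=90),
        # continuous one-year exposure (population simulations)
        "continuous_365d": ExposureSchedule(
            air_conc=0.2, hours_per_day=24.0, days_per_week=7, duration_days=365),
        # duration-extrapolation pair, continuous at the TLV
        "monkey_duration_90d": ExposureSchedule(
            air_conc=0.2, hours_per_day=24.0, days_per_week=7, duration_days=90),
        "monkey_duration_2yr": ExposureSchedule(
            air_conc=0.2, hours_per_day=24.0, days_per_week=7, duration_days=730),
        # 65 exposure days (13 five-day weeks) at 1.5 mg Mn/m^3
        "dorman_65day": ExposureSchedule(
            air_conc=1.5, hours_per_day=6.0, days_per_week=5, duration_days=89),
        # subchronic rat design (aged-rat scenario)
        "rat_subchronic": ExposureSchedule(
            air_conc=0.5, hours_per_day=6.0, days_per_week=5, duration_days=90),
    }
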