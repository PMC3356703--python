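"""Route-specific manganese fluxes.

Everything that moves manganese into or out of the body lives here:
inhalation deposition onto the nasal and lung epithelium, direct olfactory
transport to the olfactory bulb, continuous dietary input into the gut lumen,
dose-dependent absorption from the lumen into the gut epithelium, enterocyte
sloughing into feces, and inducible biliary excretion from the liver back
into the gut lumen.

Unit conventions (shared by the whole package):

* amounts      μg Mn
* time         h
* flows        L/h
* masses       g (density 1 g/mL, so μg/g == μg/mL)
* air          mg Mn/m^3, numerically identical to μg/L
* diet         mg Mn/day (or ppm of diet with a food intake in g/day)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Optional


# ---------------------------------------------------------------------------
# Exposure schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExposureSchedule:
    """Intermittent inhalation exposure plus continuous dietary intake.

    Inhalation is active for ``hours_per_day`` hours at the start of each of
    the first ``days_per_week`` days of every week, beginning at
    ``start_time`` and ending after ``duration_days`` calendar days.  Diet is
    delivered continuously (steady-feeding assumption), specified either as
    ``diet_rate`` in mg/day or as ``diet_ppm`` of the food together with
    ``food_intake`` in g/day — never both.
    """

    air_conc: float = 0.0          # mg Mn/m^3 == ug/L
    hours_per_day: float = 0.0
    days_per_week: int = 7
    duration_days: float = 0.0     # calendar days of the inhalation regimen
    diet_rate: Optional[float] = None   # mg Mn/day
    diet_ppm: Optional[float] = None    # ug Mn per g food
    food_intake: Optional[float] = None  # g food per day
    start_time: float = 0.0        # h

    def __post_init__(self) -> None:
        if not 0.0 <= self.hours_per_day <= 24.0:
            raise ValueError(f"hours_per_day must be in [0, 24], got {self.hours_per_day}")
        if not 1 <= int(self.days_per_week) <= 7:
            raise ValueError(f"days_per_week must be in 1..7, got {self.days_per_week}")
        if self.air_conc < 0:
            raise ValueError("air_conc must be >= 0")
        if self.duration_days < 0:
            raise ValueError("duration_days must be >= 0")
        if self.diet_rate is not None and self.diet_ppm is not None:
            raise ValueError("specify diet as diet_rate OR diet_ppm (+food_intake), not both")
        if (self.diet_ppm is None) != (self.food_intake is None):
            raise ValueError("diet_ppm and food_intake must be given together")
        if self.diet_mg_per_day < 0:
            raise ValueError("dietary intake must be >= 0")

    # -- diet ---------------------------------------------------------------

    @property
    def diet_mg_per_day(self) -> float:
        if self.diet_rate is not None:
            return self.diet_rate
        if self.diet_ppm is not None:
            return self.diet_ppm * self.food_intake / 1000.0
        return 0.0

    @property
    def diet_ug_per_h(self) -> float:
        """Continuous dietary input rate into the gut lumen."""
        return self.diet_mg_per_day * 1000.0 / 24.0

    # -- inhalation windows -------------------------------------------------

    def exposure_on(self, t: float) -> bool:
        """Whether inhalation is active at time ``t`` (hours)."""
        rel = t - self.start_time
        if rel < 0 or rel >= self.duration_days * 24.0 or self.air_conc == 0:
            return False
        day = math.floor(rel / 24.0)
        if day % 7 >= self.days_per_week:
            return False
        return (rel - day * 24.0) < self.hours_per_day

    def on_windows(self, t_end: float) -> list[tuple[float, float]]:
        """Exposure on-intervals ``[(t_on, t_off), ...]`` up to ``t_end``.

        Adjacent windows of a continuous (24 h/day) schedule are merged so
        that the integrator does not restart every midnight.
        """
        if self.air_conc == 0 or self.hours_per_day == 0 or self.duration_days == 0:
            return []
        last = min(t_end, self.start_time + self.duration_days * 24.0)
        windows: list[tuple[float, float]] = []
        day = 0
        while True:
            t0 = self.start_time + day * 24.0
            if t0 >= last:
                break
            if day % 7 < self.days_per_week:
                t1 = min(t0 + self.hours_per_day, last)
                if t1 > t0:
                    if windows and math.isclose(windows[-1][1], t0):
                        windows[-1] = (windows[-1][0], t1)
                    else:
                        windows.append((t0, t1))
            day += 1
        return [(a, b) for a, b in windows if b > a]

    def total_on_hours(self, t_end: float) -> float:
        return sum(b - a for a, b in self.on_windows(t_end))


def dietary_input_rate(schedule: ExposureSchedule, t: float = 0.0) -> float:
    """μg Mn/h entering the gut lumen (continuous feeding; ``t`` unused)."""
    return schedule.diet_ug_per_h


# ---------------------------------------------------------------------------
# Inhalation deposition and olfactory transport
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepositionParams:
    """Lumped regional deposition of inhaled Mn and epithelial clearance.

    Deposition fractions are particle-size-lumped constants per species; the
    fraction ``1 - (f_nasal_olf + f_nasal_resp + f_pulm)`` is exhaled and
    never enters the body.  Deposited material clears to systemic blood at
    ``k_epith_absorb``; the olfactory epithelium additionally routes a small
    flux directly to the olfactory bulb at ``k_olf_transport``.
    """

    f_nasal_olf: float
    f_nasal_resp: float
    f_pulm: float
    k_olf_transport: float   # 1/h, olfactory epithelium -> olfactory bulb
    k_epith_absorb: float    # 1/h, each respiratory epithelium -> blood

    def __post_init__(self) -> None:
        for name in ("f_nasal_olf", "f_nasal_resp", "f_pulm",
                     "k_olf_transport", "k_epith_absorb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.f_nasal_olf + self.f_nasal_resp + self.f_pulm > 1.0 + 1e-12:
            raise ValueError("deposition fractions must sum to <= 1")

    @property
    def f_deposited(self) -> float:
        return self.f_nasal_olf + self.f_nasal_resp + self.f_pulm


def inhaled_deposition_rates(air_conc: float, q_p: float, dep: DepositionParams,
                             exposure_on: bool) -> tuple[float, float, float]:
    """Deposition fluxes (μg/h) to (nasal olfactory, nasal respiratory, lung).

    ``flux_region = air_conc * q_p * f_region`` while exposure is on, zero
    otherwise.  ``air_conc`` in mg/m^3 (== μg/L), ``q_p`` in L/h.
    """
    if not exposure_on or air_conc == 0.0:
        return (0.0, 0.0, 0.0)
    base = air_conc * q_p
    return (base * dep.f_nasal_olf, base * dep.f_nasal_resp, base * dep.f_pulm)


def olfactory_transport_flux(a_olf_epith: float, k_olf_transport: float) -> float:
    """μg/h delivered from the olfactory epithelium directly to the bulb."""
    if a_olf_epith < 0:
        raise ValueError("epithelial amount must be >= 0")
    return k_olf_transport * a_olf_epith


# ---------------------------------------------------------------------------
# Gut: absorption, sloughing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GutParams:
    """Gastrointestinal handling of manganese.

    Lumen Mn is taken up into the gut epithelium at ``k_abs``, inhibited at
    high lumen loads (Hill term with half-inhibition amount ``K_inh`` and
    exponent ``n_inh`` — this is what makes the absorbed fraction F_dietup
    fall as dietary Mn rises), or passes to feces at ``k_fec``.  Epithelial
    Mn either enters the portal circulation at ``k_absorb_portal`` or is lost
    with sloughed enterocytes at ``k_slough`` (fecal, never systemic).
    """

    k_abs: float            # 1/h  lumen -> epithelium (basal)
    k_fec: float            # 1/h  lumen -> feces
    K_inh: float            # ug   lumen amount at half-maximal uptake inhibition
    n_inh: float = 1.0
    k_slough: float = 0.0   # 1/h  epithelium -> feces
    k_absorb_portal: float = 0.0  # 1/h  epithelium -> liver (portal blood)

    def __post_init__(self) -> None:
        for name in ("k_abs", "k_fec", "k_slough", "k_absorb_portal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.K_inh <= 0:
            raise ValueError("K_inh must be > 0")
        if self.n_inh < 1:
            raise ValueError("n_inh must be >= 1")
        if not 0.0 < self.f_dietup0 < 1.0:
            raise ValueError("basal absorbed fraction must lie in (0, 1)")

    @property
    def f_dietup0(self) -> float:
        """Basal (trace-level) fraction of lumen Mn absorbed into epithelium."""
        return self.k_abs / (self.k_abs + self.k_fec)


def gut_absorption_flux(a_lumen: float, gut: GutParams) -> float:
    """μg/h lumen→epithelium with dose-dependent uptake inhibition."""
    if a_lumen < 0:
        raise ValueError("lumen amount must be >= 0")
    return gut.k_abs * a_lumen / (1.0 + (a_lumen / gut.K_inh) ** gut.n_inh)


def enterocyte_sloughing_flux(a_epith: float, k_slough: float) -> float:
    """μg/h epithelium→feces via shedding of enterocytes."""
    if a_epith < 0:
        raise ValueError("epithelial amount must be >= 0")
    return k_slough * a_epith


# ---------------------------------------------------------------------------
# Biliary excretion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiliaryParams:
    """Basal biliary clearance of liver free Mn, inducible at high liver Mn.

    The induction factor is ``1 + i_max * cf^n / (c50^n + cf^n)`` where ``cf``
    is the liver free concentration; it saturates at ``1 + i_max``.
    """

    k_bile_c: float          # mL/h, applied to liver free conc (μg/mL)
    i_max: float = 0.0       # maximal fold-induction above basal
    c50_ind: float = 1.0     # ug/g liver free conc at half-maximal induction
    n_ind: float = 1.0

    def __post_init__(self) -> None:
        if self.k_bile_c < 0 or self.i_max < 0:
            raise ValueError("k_bile_c and i_max must be >= 0")
        if self.c50_ind <= 0:
            raise ValueError("c50_ind must be > 0")
        if self.n_ind < 1:
            raise ValueError("n_ind must be >= 1")

    def induction_factor(self, cf_liver: float) -> float:
        if cf_liver <= 0:
            return 1.0
        h = cf_liver ** self.n_ind
        return 1.0 + self.i_max * h / (self.c50_ind ** self.n_ind + h)


def biliary_excretion_flux(cf_liver: float, bile: BiliaryParams) -> float:
    """μg/h liver→gut lumen: ``k_bile_c * cf * induction_factor(cf)``."""
    if cf_liver < 0:
        raise ValueError("liver free concentration must be >= 0")
    return bile.k_bile_c * cf_liver * bile.induction_factor(cf_liver)
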