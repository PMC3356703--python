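"""Scenario modifiers, dose metrics and pharmacokinetic CSAFs.

A *scenario* is a named bundle of multiplicative parameter modifiers applied
to a species parameter set — e.g. moderate hepatobiliary impairment (liver
blood flow ×0.5 and biliary excretion ×0.5) or the aged rat (minute volume
×0.75).  Dose metrics extracted from simulated time courses (end-of-exposure
concentration, average daily AUC, Cmax, percent change from basal) feed the
chemical-specific adjustment factor (CSAF): the ratio of an internal dose
metric in a potentially susceptible subpopulation to the same metric in the
baseline population.  A CSAF > 1 means the susceptible group attains the
higher internal dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import TimeCourse
from .fluxes import ExposureSchedule
from .species import SpeciesParameterSet


@dataclass(frozen=True)
class Scenario:
    """Named multiplicative modifiers on parameter paths.

    ``modifiers`` maps dotted parameter paths (see
    :meth:`SpeciesParameterSet.get`) to positive factors.  An optional
    ``schedule`` overrides the exposure design of the baseline run.
    """

    name: str
    modifiers: Mapping[str, float] = field(default_factory=dict)
    schedule: Optional[ExposureSchedule] = None

    def __post_init__(self) -> None:
        for path, f in self.modifiers.items():
            if not f > 0:
                raise ValueError(f"scenario factor for {path!r} must be > 0")


#: Scenarios shipped with the package.
NAMED_SCENARIOS: dict[str, Scenario] = {
    # moderate hepatobiliary disease: halved liver perfusion and biliary excretion
    "hepatic_impaired": Scenario(
        name="hepatic_impaired",
        modifiers={"tissue.liver.q_blood": 0.5, "bile.k_bile_c": 0.5},
    ),
    # aged rat: 25% decline in pulmonary minute volume
    "aged_rat": Scenario(name="aged_rat", modifiers={"model.q_p": 0.75}),
}


def get_scenario(name: str) -> Scenario:
    try:
        return NAMED_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; shipped: {sorted(NAMED_SCENARIOS)}")


def apply_scenario(params: SpeciesParameterSet, scenario: Scenario,
                   ) -> SpeciesParameterSet:
    """Return a new parameter set with the scenario factors applied.

    The original set is untouched.  Changes to any tissue blood flow are
    re-balanced into the rest-of-body residual flow so cardiac output is
    conserved; a modifier that would drive the residual flow negative is
    rejected.
    """
    out = params.copy()
    flow_delta = 0.0
    for path, factor in scenario.modifiers.items():
        old = out.get(path)  # raises KeyError for unknown paths
        out.set(path, old * factor)
        if path.startswith("tissue.") and path.endswith(".q_blood") \
                and not path.startswith("tissue.rest_of_body"):
            flow_delta += old * factor - old
    if flow_delta != 0.0:
        rest = out.model["rest_of_body"]
        new_q = rest.q_blood - flow_delta
        if new_q < 0:
            raise ValueError(
                f"scenario {scenario.name!r} drives rest-of-body blood flow "
                f"negative ({new_q:.3g} L/h)")
        rest.q_blood = new_q
    # re-validate whole-model flow balance
    if out.model.residual_flow < -1e-9:
        raise ValueError("scenario makes tissue flows exceed cardiac output")
    return out


# ---------------------------------------------------------------------------
# Dose metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseMetrics:
    """Internal dose metrics for one tissue in one simulation."""

    end_of_exposure_conc: float      # μg/g
    avg_daily_auc: float             # μg·h/g/day
    c_max: float                     # μg/g
    pct_change_from_basal: float     # %

    def __post_init__(self) -> None:
        if self.end_of_exposure_conc > self.c_max * (1 + 1e-9):
            raise ValueError("end-of-exposure concentration exceeds Cmax")
        if self.avg_daily_auc > 24.0 * self.c_max * (1 + 1e-9):
            raise ValueError("average daily AUC exceeds 24 h * Cmax")


def end_of_exposure_concentration(tc: TimeCourse, tissue: str) -> float:
    """Total concentration at the end of the final inhalation on-phase.

    For a continuous schedule whose exposure still runs at the end of the
    simulation this is the final grid value; schedules with no exposure at
    all are rejected (there is no 'end of exposure' for a diet-only run).
    """
    t_end = tc.times[-1]
    windows = tc.schedule.on_windows(t_end)
    if not windows:
        raise ValueError("schedule has no inhalation exposure")
    t_eoe = min(windows[-1][1], t_end)
    conc = tc.conc(tissue)
    return float(np.interp(t_eoe, tc.times, conc))


def average_daily_auc(tc: TimeCourse, tissue: str,
                      window_days: Optional[float] = None) -> float:
    """Trapezoidal daily-average AUC (μg·h/g/day) over the final window."""
    duration_h = tc.times[-1] - tc.times[0]
    if window_days is None:
        window_days = duration_h / 24.0
    if window_days <= 0:
        raise ValueError("window must be positive")
    if window_days * 24.0 > duration_h * (1 + 1e-9):
        raise ValueError(
            f"window of {window_days} d exceeds simulated duration "
            f"{duration_h / 24.0:.3g} d")
    t0 = tc.times[-1] - window_days * 24.0
    mask = tc.times >= t0 - 1e-9
    t = tc.times[mask]
    c = tc.conc(tissue)[mask]
    return float(np.trapezoid(c, t) / window_days)


def c_max(tc: TimeCourse, tissue: str) -> float:
    return float(tc.conc(tissue).max())


def percent_change_from_basal(exposed: float, basal: float) -> float:
    """100·(exposed − basal)/basal."""
    if basal <= 0:
        raise ValueError("basal concentration must be > 0")
    return 100.0 * (exposed - basal) / basal


def compute_csaf(metric_susceptible: float, metric_baseline: float) -> float:
    """Pharmacokinetic chemical-specific adjustment factor.

    Ratio of an internal dose metric (end-of-exposure concentration, AUC,
    Cmax) in the susceptible subpopulation over the baseline population.
    """
    if metric_baseline <= 0:
        raise ValueError("baseline metric must be > 0")
    return metric_susceptible / metric_baseline


def compute_dose_metrics(tc: TimeCourse, tissue: str, basal: float) -> DoseMetrics:
    eoe = end_of_exposure_concentration(tc, tissue)
    return DoseMetrics(
        end_of_exposure_conc=eoe,
        avg_daily_auc=average_daily_auc(tc, tissue),
        c_max=c_max(tc, tissue),
        pct_change_from_basal=percent_change_from_basal(eoe, basal),
    )


def metrics_frame(rows: list[tuple[str, str, str, float]]) -> pd.DataFrame:
    """Flat (scenario, tissue, metric, value) table for CSV export."""
    return pd.DataFrame(rows, columns=["scenario", "tissue", "metric", "value"])
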