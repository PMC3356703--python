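"""Monte Carlo population variability for the adult human model.

Simulates inter-individual variability in dietary manganese intake and
physiology and summarizes the resulting distribution of globus pallidus
concentrations across inhalation levels.  Default distributions:

* dietary Mn intake: normal, mean 2.43 mg/day, SD 1.8, hard range 0.07–6.2
* body weight: normal, mean 70 kg, CV 0.30
* tissue volumes and tissue blood flows: CV 0.30 (as multipliers)
* cardiac output and pulmonary ventilation (per kg): CV 0.50

All distributions are truncated at ±2 SD and sampled independently (no
parameter correlations).  Derived quantities — compartment masses, flows,
cardiac output and ventilation — are recomputed from the sampled body
weight; rest-of-body mass and blood flow are residuals, and subjects whose
residuals would be negative are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import SolverSettings, simulate, steady_state
from .species import SpeciesParameterSet


@dataclass(frozen=True)
class DistSpec:
    """One truncated-normal sampling entry."""

    mean: float
    sd: float
    truncation_k: float = 2.0
    hard_bounds: Optional[tuple[float, float]] = None


@dataclass
class ParameterDistributions:
    """Sampling specification for a human population.

    ``diet`` and ``body_weight`` are absolute; the remaining entries are
    unitless multipliers (mean 1) applied to per-tissue masses, per-tissue
    flows, and the per-kg cardiac output / ventilation of the base set.
    """

    diet: DistSpec = field(default_factory=lambda: DistSpec(
        mean=2.43, sd=1.8, hard_bounds=(0.07, 6.2)))
    body_weight: DistSpec = field(default_factory=lambda: DistSpec(mean=70.0, sd=21.0))
    volume_cv: float = 0.30
    flow_cv: float = 0.30
    qc_qp_cv: float = 0.50
    truncation_k: float = 2.0


def sample_truncated_normal(mean: float, sd: float, n: int,
                            rng: np.random.Generator,
                            truncation_k: float = 2.0,
                            hard_bounds: Optional[tuple[float, float]] = None,
                            ) -> np.ndarray:
    """Rejection-sample a normal truncated at ±k·SD and optional hard bounds."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    lo = mean - truncation_k * sd
    hi = mean + truncation_k * sd
    if hard_bounds is not None:
        lo, hi = max(lo, hard_bounds[0]), min(hi, hard_bounds[1])
    if lo > hi:
        raise ValueError(f"empty feasible interval [{lo}, {hi}]")
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


@dataclass
class Subject:
    params: SpeciesParameterSet
    diet_mg_per_day: float


def _draw_subject(dists: ParameterDistributions, base: SpeciesParameterSet,
                  rng: np.random.Generator) -> Subject:
    """One feasible subject; redraws until residual mass/flow are positive."""
    k = dists.truncation_k
    base_bw = base.body_weight
    tissues = [c.name for c in base.model.compartments]
    var_tissues = [t for t in tissues if t not in ("blood", "rest_of_body")]

    for attempt in range(1_000_000):
        bw = sample_truncated_normal(dists.body_weight.mean, dists.body_weight.sd,
                                     1, rng, k)[0]
        if bw <= 0:
            continue
        vol_m = {t: sample_truncated_normal(1.0, dists.volume_cv, 1, rng, k)[0]
                 for t in var_tissues}
        vol_m["blood"] = sample_truncated_normal(1.0, dists.volume_cv, 1, rng, k)[0]
        flow_m = {t: sample_truncated_normal(1.0, dists.flow_cv, 1, rng, k)[0]
                  for t in var_tissues}
        qc_m = sample_truncated_normal(1.0, dists.qc_qp_cv, 1, rng, k)[0]
        qp_m = sample_truncated_normal(1.0, dists.qc_qp_cv, 1, rng, k)[0]
        if qc_m <= 0 or qp_m <= 0:
            continue

        p = base.copy()
        scale_bw = bw / base_bw
        total_mass = bw * 1000.0
        other_mass = 0.0
        for t in var_tissues + ["blood"]:
            c = p.model[t]
            c.mass = base.model[t].mass * scale_bw * vol_m[t]
            other_mass += c.mass
        rest_mass = total_mass - other_mass
        if rest_mass <= 0:
            continue
        p.model["rest_of_body"].mass = rest_mass

        q_c = base.model.q_c / base_bw * bw * qc_m
        q_p = base.model.q_p / base_bw * bw * qp_m
        other_flow = 0.0
        for t in var_tissues:
            c = p.model[t]
            c.q_blood = base.model[t].q_blood / base.model.q_c * q_c * flow_m[t]
            other_flow += c.q_blood
        rest_flow = q_c - other_flow
        if rest_flow <= 0:
            continue
        p.model["rest_of_body"].q_blood = rest_flow
        p.model.q_c = q_c
        p.model.q_p = q_p
        p.body_weight = bw

        diet = sample_truncated_normal(
            dists.diet.mean, dists.diet.sd, 1, rng,
            dists.diet.truncation_k, dists.diet.hard_bounds)[0]
        return Subject(params=p, diet_mg_per_day=diet)
    raise RuntimeError("could not draw a feasible subject in 10^6 attempts")


def sample_population(dists: ParameterDistributions, base: SpeciesParameterSet,
                      n: int, seed: int) -> list[Subject]:
    """Draw ``n`` independent subjects, reproducibly for a given seed."""
    if base.species != "human":
        raise ValueError("population sampling is defined for the human set")
    rng = np.random.default_rng(seed)
    return [_draw_subject(dists, base, rng) for _ in range(n)]


def summarize_distribution(values: Sequence[float]) -> dict[str, float]:
    """Empirical min/p5/median/p95/max with linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value set")
    q = np.percentile(v, [0, 5, 50, 95, 100])
    return {"min": float(q[0]), "p5": float(q[1]), "median": float(q[2]),
            "p95": float(q[3]), "max": float(q[4])}


@dataclass
class PopulationResult:
    """Per-subject pallidal metrics and per-air-level summaries."""

    air_levels: list[float]
    values: np.ndarray            # (n_air, n_subjects), NaN where failed
    summaries: list[dict[str, float]]
    n: int
    seed: int
    n_failed: int = 0


def run_population(dists: ParameterDistributions, base: SpeciesParameterSet,
                   n: int, seed: int,
                   air_levels: Sequence[float] = (0.00005, 0.0005, 0.005,
                                                  0.05, 0.2, 0.5),
                   duration_days: float = 365.0,
                   solver: SolverSettings = SolverSettings(),
                   tissue: Optional[str] = None) -> PopulationResult:
    """Continuous-exposure population simulation.

    Each subject starts from its own diet-only steady state and inhales
    continuously (24 h/d, 7 d/wk) for ``duration_days``; the end-of-exposure
    target-tissue concentration is recorded.  Subjects whose integration
    fails are excluded and counted.
    """
    tissue = tissue or base.target_tissue
    subjects = sample_population(dists, base, n, seed)
    values = np.full((len(air_levels), n), np.nan)
    n_failed = 0
    for j, subj in enumerate(subjects):
        try:
            diet_ug_h = subj.diet_mg_per_day * 1000.0 / 24.0
            ss = steady_state(subj.params, diet_ug_h)
            for i, air in enumerate(air_levels):
                sched = subj.params.default_schedule(
                    air_conc=air, hours_per_day=24.0, days_per_week=7,
                    duration_days=duration_days)
                sched = type(sched)(air_conc=air, hours_per_day=24.0,
                                    days_per_week=7, duration_days=duration_days,
                                    diet_rate=subj.diet_mg_per_day)
                if air == 0.0:
                    values[i, j] = _state_conc(subj.params, ss, tissue)
                else:
                    tc = simulate(subj.params, sched, initial=ss, solver=solver,
                                  n_out=16)
                    values[i, j] = tc.conc(tissue)[-1]
        except Exception:
            n_failed += 1
            values[:, j] = np.nan
    summaries = [summarize_distribution(row[~np.isnan(row)]) for row in values]
    return PopulationResult(air_levels=list(air_levels), values=values,
                            summaries=summaries, n=n, seed=seed,
                            n_failed=n_failed)


def _state_conc(params: SpeciesParameterSet, state, tissue: str) -> float:
    i = params.model.names.index(tissue)
    return float((state.a_free[i] + state.a_bound[i]) / params.model[tissue].mass)
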