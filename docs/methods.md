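# Methods

## Model

`mnpbpk` simulates whole-body manganese (Mn) kinetics in the adult rat,
rhesus monkey and adult human with a physiologically based compartmental
model.  The state is the *amount* (μg) of free and bound Mn in fourteen
compartments: blood, liver, gut lumen, gut epithelium, lung epithelium,
nasal olfactory and respiratory epithelium, olfactory bulb, a basal-ganglia
target region (striatum in the rat, globus pallidus in the primates),
cerebellum, pituitary, bone, kidney and rest-of-body.  Working in amounts
rather than concentrations lets conservation be checked exactly at every
output time:

    body(t) + cumulative fecal(t) = body(0) + cumulative intake(t).

Free Mn exchanges between blood and each tissue by asymmetric diffusional
fluxes: influx `k_in·C_blood` and efflux `k_out·C_free`, with the flux
coefficients in mL/h applied to concentrations in μg/mL (tissue density is
fixed at 1 g/mL so μg/g and μg/mL interchange).  Influx is additionally
capped at the perfusion delivery limit `q_blood·C_blood`.  Within each
tissue, free Mn binds reversibly to a saturable pool:

    d(bound)/dt = k_a·C_free·(B_max·mass − bound) − k_d·bound.

The bound pool dominates basal tissue levels; free Mn is the transient
species that rises during inhalation and washes out afterwards.  Because
capacity is finite, tissue concentrations flatten as the pool fills — this
saturation, together with the two homeostatic processes below, produces the
dose-dependent threshold behaviour the model exists to capture.

### Routes

*Diet* enters the gut lumen continuously at `mg/day·1000/24` μg/h (meal
structure is irrelevant on the ≥90-day horizons simulated here).  Lumen Mn
is either taken up into the gut epithelium — at a rate inhibited by the
lumen load, `k_abs·A/(1+(A/K_inh)^n)`, which makes the absorbed fraction
F_dietup fall as dietary Mn rises — or passes to feces at `k_fec`.
Epithelial Mn splits between portal uptake (`k_absorb_portal`, delivered to
the liver free pool: a first-pass architecture, so most absorbed Mn is
extracted and re-secreted in bile before ever reaching the systemic
circulation) and loss with sloughed enterocytes (`k_slough`, fecal, never
systemic).

*Bile* clears liver free Mn into the gut lumen at `k_bile_c·C_free·f_ind`,
where the induction factor `f_ind = 1 + i_max·C^n/(c50^n + C^n)` rises with
liver free Mn.  Gut uptake inhibition and biliary induction are the two
homeostatic controls; jointly they hold tissue Mn nearly constant across an
order of magnitude of dietary intake.  Bile-returned Mn re-enters the lumen
pool and can be reabsorbed (enterohepatic recirculation); setting `k_abs`
to zero disables the loop if a sensitivity analysis needs it.

*Inhalation* deposits `air·q_p·f_region` μg/h on the nasal olfactory, nasal
respiratory and lung epithelium while a schedule is on; the rest is exhaled
and never counted as intake.  Deposition fractions are lumped per-species
constants — no particle-size model.  Deposited Mn is absorbed into systemic
blood at `k_epith_absorb`; the olfactory epithelium routes a small parallel
flux (`k_olf_transport`) directly to the olfactory bulb.  Inhaled Mn thus
bypasses both the gut absorption barrier and hepatic first pass, which is
why air concentrations reaching the low mg/m³ range move brain Mn while
dietary variation of similar magnitude does not.

Urinary excretion is not modelled (elimination is biliary/fecal only); this
is a documented limitation shared with the elimination data the model
family was built on.

### Integration

Schedules are integrated piecewise with LSODA (rtol 1e-8, atol 1e-10 μg by
default), restarting at every exposure on/off transition; transitions are
explicit so no event detection is needed.  Output grids always contain the
transition times, so end-of-exposure values are exact grid points.  The
solver is verified against a closed-form infusion–elimination fixture
(agreement better than 1e-6 relative) and a fixed-step RK4 oracle.

The diet-only steady state used as the default initial condition is solved
algebraically: for a trial blood concentration the liver/bile/lumen
subsystem (including the recirculation fixed point) is resolved by nested
1-D bracketing, and the whole-body balance `fecal = intake` closes the
outer root.  The algebraic state is required to agree with a forward
integration within 0.1% (`verify=True`), and the test suite checks it stays
put over 30 simulated days.

## Parameters

Physiology (masses, flows, ventilation) uses standard reference values; the
human follows the 70-kg reference (blood 8%, bone 12%, brain 2%, liver 3%,
lung 1% of body weight; cardiac output 13 L/h/kg; ventilation 20 L/h/kg).
The printed source for those fractions lists a remainder of "0.74%", which
cannot be literal (the named fractions sum to ~26%); rest-of-body mass and
blood flow are therefore computed as residuals, which also guarantees both
stay non-negative under scenario modifiers and Monte Carlo sampling.

No published table provides the kinetic constants, so they are calibrated
(`mnpbpk.calibrate`, weighted least squares on log concentrations) against
the numeric anchors the source analysis reports:

* **monkey** — basal globus pallidus 0.48 μg/g on a 133-ppm diet; the
  subchronic inhalation trajectory 1.92/2.41/2.94 μg/g after 15/33/65
  exposure days at 1.5 mg Mn/m³ (6 h/d, 5 d/wk); a 2-yr/90-day continuous
  end-of-exposure ratio of 1.06 at 0.2 mg/m³.  The calibrated set
  reproduces 0.480, 1.81/2.49/2.94 (each within one reported SEM) and
  1.056.
* **human** — end-of-exposure pallidal concentrations of 0.68 (normal) and
  0.85 μg/g (hepatobiliary-impaired) after one year at the 0.2 mg/m³
  occupational level, and the subchronic dose-response checkpoints (<1%
  change at 0.001 mg/m³, ~5% at 0.01, >30% above 0.1).  Biliary clearance
  and pallidal diffusional fluxes are tied to the monkey values by
  allometric BW^0.75 scaling; the remaining degrees of freedom (gut uptake,
  liver efflux, induction shape, deposition multiplier, pallidal binding)
  were fitted.  The shipped set gives 0.684/0.850 (CSAF 1.243) and
  0.5%/5.0%/35.6%, with basal tissue concentrations inside the normal human
  range (0.15–4 μg/g).
* **rat** — no quantitative anchors; rodent-scale turnover was chosen
  (subchronic striatal response of ~1.3× with full washout to within 5% of
  baseline 60 days after exposure ends) and the set is used only for ratio
  metrics (the aged/adult CSAF), which are insensitive to its absolute
  scale.

Pallidal binding is calibrated per species, and both the kinetics and the
capacity genuinely differ: the monkey anchors require a large,
weakly saturating pool (≈12 μg/g, half-saturation ≈4 μg/g free) to
accommodate a six-fold concentration rise, while the human anchor pattern —
a strong response between 0.01 and 0.1 mg/m³ that flattens hard by
0.2 mg/m³ — requires a small pool (≈0.46 μg/g, half-saturation ≈0.011 μg/g
free) saturating near the occupational level.  A shared per-gram capacity cannot satisfy both anchor
sets (bounded least-squares stalls far from the targets), so capacity is a
per-species calibrated quantity; within a species, total capacity scales
with tissue volume.  This mirrors the source analysis's own observation
that monkey–human response differences likely reflect different proximity
to binding-site saturation.

Every calibrated value is tagged in the `provenance` block of the shipped
YAML files.  Anchors exist only for the target brain region; other tissues
are constrained only by the normal-range check and should be treated as
low-confidence.

## Scenarios and dose metrics

Scenarios are multiplicative modifiers on named parameter paths: hepatic
impairment (liver blood flow ×0.5, biliary excretion ×0.5) and the aged rat
(minute volume ×0.75).  Flow modifiers are rebalanced into the rest-of-body
residual so cardiac output is conserved.  Dose metrics are total
(free+bound) concentrations; "end of exposure" means the end of the last
inhalation on-phase for intermittent schedules and the final time for
continuous ones.  The duration-extrapolation CSAF compares end-of-exposure
concentrations (not AUCs), matching how the chronic-vs-subchronic
comparison is reported.  A pharmacokinetic CSAF is the ratio of a dose
metric in the susceptible group over the baseline group; it is
scale-invariant and dimensionless.

## Monte Carlo population

Scenario-3-style variability: dietary intake Normal(2.43, 1.8²) mg/day
truncated to ±2 SD and to the reported range 0.07–6.2; body weight, tissue
volumes and blood flows CV 0.30; cardiac output and ventilation CV 0.50 —
all truncated at ±2 SD, sampled independently (no correlations, matching
the source analysis).  Volumes and flows are resampled as multipliers and
rebuilt from the sampled body weight; rest-of-body mass and flow are
residuals, and infeasible subjects (negative residuals) are redrawn.
Clearances are not resampled.  Each subject starts at its own diet-only
steady state and inhales continuously for 365 days.  The reference
population size is 10,000; summaries (min/p5/median/p95/max) are stable
from a few hundred subjects, and the test suite uses n = 500 over six air
levels, which it labels a scaled-down design.  The full pipeline is
bit-reproducible for a given seed.

## Synthetic data

The synthetic-observation generator applies multiplicative lognormal noise,
`observed = true·exp(ε)`, `ε ~ N(0, ln(1+cv²))`, default CV 0.15 — the
magnitude of the SEM/mean ratios in the published monkey tissue data.  The
generator retains the ground truth beside every noisy value so recovery
studies can compute exact errors.  It emulates tissue-sampling designs
(destructive sampling at a few time points), not inter-animal physiological
variability (that is the population module's job); passing recovery tests
therefore demonstrates identifiability under observation noise, not
robustness to model misspecification.

## Numerical choices and limitations

* Tolerances: rtol 1e-8 / atol 1e-10 μg default; mass-balance residual
  stays below 1e-6 (in practice ~1e-14) on all shipped scenarios.
* Calibration fits in log-parameter and log-concentration space with a
  trust-region local search from documented starting points; anchors
  sharing a schedule are simulated once per objective evaluation.
* Degenerate inputs: zero diet and zero air give the empty steady state;
  zero-SD distributions collapse to point masses; schedules validate their
  bounds at construction.
* The aged scenario reduces minute volume only; aged-human extrapolation is
  deliberately out of scope.  No tracer (⁵⁴Mn) bookkeeping, no CFD airway
  geometry, no nanoparticle kinetics, no pharmacodynamic endpoint modelling.
* Blood is modelled as a single free pool without erythrocyte binding, so
  its absolute concentration is an exchangeable-pool abstraction and is
  excluded from the normal-tissue-range check.
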