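species: rat
body_weight: 0.25
target_tissue: striatum
default_diet:
  diet_ppm: 125.0
  food_intake: 18.0
model:
  q_c: 5.0
  q_p: 7.0
  oral: true
  inhalation: true
  compartments:
  - name: blood
    mass: 20
    q_blood: 0
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: liver
    mass: 10
    q_blood: 1.2
    k_in: 20.0
    k_out: 2.0
    b_max: 2.5
    k_a: 0.01
    k_d: 0.006
  - name: gut_lumen
    mass: 5
    q_blood: 0
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: gut_epithelium
    mass: 2.5
    q_blood: 0.3
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: lung_epithelium
    mass: 1.5
    q_blood: 0.08
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: nasal_olfactory
    mass: 0.1
    q_blood: 0.01
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: nasal_respiratory
    mass: 0.2
    q_blood: 0.02
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: olfactory_bulb
    mass: 0.06
    q_blood: 0.004
    k_in: 0.0012
    k_out: 0.0017
    b_max: 2.5
    k_a: 0.01
    k_d: 0.004
  - name: striatum
    mass: 0.1
    q_blood: 0.01
    k_in: 0.0008670444360212627
    k_out: 0.0010573712634405642
    b_max: 2.5
    k_a: 0.01
    k_d: 0.004
  - name: cerebellum
    mass: 0.25
    q_blood: 0.025
    k_in: 0.0032355560661281265
    k_out: 0.005286856317202822
    b_max: 1.8
    k_a: 0.01
    k_d: 0.004
  - name: pituitary
    mass: 0.01
    q_blood: 0.004
    k_in: 0.0002590559595429382
    k_out: 0.00021147425268811285
    b_max: 3.0
    k_a: 0.01
    k_d: 0.004
  - name: bone
    mass: 15
    q_blood: 0.2
    k_in: 0.123
    k_out: 0.3
    b_max: 3.0
    k_a: 0.006
    k_d: 0.003
  - name: kidney
    mass: 2
    q_blood: 0.7
    k_in: 0.06344227580643386
    k_out: 0.03172113790321693
    b_max: 1.5
    k_a: 0.01
    k_d: 0.005
  - name: rest_of_body
    mass: 193.38
    q_blood: 2.2
    k_in: 0.61
    k_out: 1.0
    b_max: 0.8
    k_a: 0.006
    k_d: 0.003
dep:
  f_nasal_olf: 0.005
  f_nasal_resp: 0.26
  f_pulm: 0.1
  k_olf_transport: 0.01
  k_epith_absorb: 0.05
gut:
  k_abs: 0.002
  k_fec: 0.15
  K_inh: 800.0
  n_inh: 1.0
  k_slough: 0.01
  k_absorb_portal: 0.04
bile:
  k_bile_c: 0.13889205968049875
  i_max: 2.0
  c50_ind: 0.5
  n_ind: 1.0
provenance:
  bile.k_bile_c: 'scaled: allometric BW^0.75 from monkey'
  tissue.striatum.k_in: 'scaled: allometric BW^0.75 from monkey'
  tissue.striatum.k_out: 'scaled: allometric BW^0.75 from monkey'
  model: 'assumed: standard physiology / plausible default'
  dep: 'assumed: standard physiology / plausible default'
  tissue.liver.k_in: 'assumed: fast hepatic uptake, rodent-scale turnover'
  note: no quantitative anchors for the rat; kinetics chosen for rodent-scale turnover
    (subchronic response with full washout inside 60 days); used for ratio metrics
    only
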