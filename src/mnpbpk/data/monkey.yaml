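species: monkey
body_weight: 5.0
target_tissue: globus_pallidus
default_diet:
  diet_ppm: 133.0
  food_intake: 150.0
model:
  q_c: 70.0
  q_p: 60.0
  oral: true
  inhalation: true
  compartments:
  - name: blood
    mass: 400
    q_blood: 0
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: liver
    mass: 150
    q_blood: 16
    k_in: 10.0
    k_out: 1.0
    b_max: 2.5
    k_a: 0.005
    k_d: 0.0015
  - name: gut_lumen
    mass: 60
    q_blood: 0
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: gut_epithelium
    mass: 40
    q_blood: 4
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: lung_epithelium
    mass: 25
    q_blood: 1
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: nasal_olfactory
    mass: 0.6
    q_blood: 0.05
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: nasal_respiratory
    mass: 2.5
    q_blood: 0.2
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: olfactory_bulb
    mass: 0.15
    q_blood: 0.02
    k_in: 0.00286
    k_out: 0.004
    b_max: 2.0
    k_a: 0.0006260232
    k_d: 9.390348e-05
  - name: globus_pallidus
    mass: 0.4
    q_blood: 0.05
    k_in: 0.0082
    k_out: 0.01
    b_max: 11.9995
    k_a: 0.000521686
    k_d: 0.00227793
  - name: cerebellum
    mass: 6
    q_blood: 0.6
    k_in: 0.0306
    k_out: 0.05
    b_max: 1.8
    k_a: 0.002
    k_d: 0.0002
  - name: pituitary
    mass: 0.06
    q_blood: 0.05
    k_in: 0.00245
    k_out: 0.002
    b_max: 3.0
    k_a: 0.0025
    k_d: 0.0003
  - name: bone
    mass: 700
    q_blood: 2.8
    k_in: 0.041
    k_out: 0.1
    b_max: 3.0
    k_a: 0.001
    k_d: 0.0001
  - name: kidney
    mass: 25
    q_blood: 9
    k_in: 0.6
    k_out: 0.3
    b_max: 1.5
    k_a: 0.003
    k_d: 0.0006
  - name: rest_of_body
    mass: 3590.29
    q_blood: 36.23
    k_in: 0.61
    k_out: 1.0
    b_max: 0.8
    k_a: 0.0015
    k_d: 0.000225
dep:
  f_nasal_olf: 0.01
  f_nasal_resp: 0.15
  f_pulm: 0.25
  k_olf_transport: 0.005
  k_epith_absorb: 0.05
gut:
  k_abs: 0.0005
  k_fec: 0.06
  K_inh: 25000.0
  n_inh: 1.0
  k_slough: 0.0086
  k_absorb_portal: 0.02
bile:
  k_bile_c: 1.31356
  i_max: 0.500002
  c50_ind: 0.0500072
  n_ind: 1.0
provenance:
  gut.k_abs: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  bile.k_bile_c: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  bile.i_max: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  bile.c50_ind: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  tissue.globus_pallidus.k_a: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  tissue.globus_pallidus.k_d: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  tissue.globus_pallidus.b_max: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  model: 'assumed: standard physiology / plausible default'
  dep: 'assumed: standard physiology / plausible default'
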