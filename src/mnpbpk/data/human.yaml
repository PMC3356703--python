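species: human
body_weight: 70.0
target_tissue: globus_pallidus
default_diet:
  diet_rate: 2.43
model:
  q_c: 910.0
  q_p: 1400.0
  oral: true
  inhalation: true
  compartments:
  - name: blood
    mass: 5600
    q_blood: 0
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: liver
    mass: 2100
    q_blood: 209.3
    k_in: 72.4
    k_out: 125.64853467293726
    b_max: 2.5
    k_a: 0.005
    k_d: 0.0015
  - name: gut_lumen
    mass: 250
    q_blood: 0
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: gut_epithelium
    mass: 300
    q_blood: 100
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: lung_epithelium
    mass: 700
    q_blood: 20
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: nasal_olfactory
    mass: 2.0
    q_blood: 2.0
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: nasal_respiratory
    mass: 15.0
    q_blood: 7.1
    k_in: 0.0
    k_out: 0.0
    b_max: 0.0
    k_a: 0.0
    k_d: 0.0
  - name: olfactory_bulb
    mass: 0.7
    q_blood: 0.3
    k_in: 0.02069960508444511
    k_out: 0.028950496621601554
    b_max: 2.0
    k_a: 0.11999883741994541
    k_d: 0.0023999767483989082
  - name: globus_pallidus
    mass: 15.0
    q_blood: 2.0
    k_in: 0.05934851807428319
    k_out: 0.07237624155400388
    b_max: 0.46110768900617116
    k_a: 0.09999903118328785
    k_d: 0.0010940728018080594
  - name: cerebellum
    mass: 150
    q_blood: 15
    k_in: 0.22147129915525185
    k_out: 0.3618812077700194
    b_max: 1.8
    k_a: 0.002
    k_d: 6.0e-05
  - name: pituitary
    mass: 0.6
    q_blood: 0.3
    k_in: 0.017732179180730948
    k_out: 0.014475248310800777
    b_max: 3.0
    k_a: 0.0025
    k_d: 8.0e-05
  - name: bone
    mass: 8400
    q_blood: 36.4
    k_in: 0.2967425903714159
    k_out: 0.7237624155400388
    b_max: 3.0
    k_a: 0.001
    k_d: 3.0e-05
  - name: kidney
    mass: 300
    q_blood: 170
    k_in: 4.342574493240233
    k_out: 2.1712872466201163
    b_max: 1.5
    k_a: 0.003
    k_d: 0.00018
  - name: rest_of_body
    mass: 52166.7
    q_blood: 347.6
    k_in: 4.414950734794236
    k_out: 7.237624155400388
    b_max: 0.8
    k_a: 0.0015
    k_d: 7.0e-05
dep:
  f_nasal_olf: 0.0023542615763827617
  f_nasal_resp: 0.03531392364574142
  f_pulm: 0.05885653940956904
  k_olf_transport: 0.002
  k_epith_absorb: 0.05
gut:
  k_abs: 0.0029739276181254774
  k_fec: 0.1
  K_inh: 3000.0
  n_inh: 1.0
  k_slough: 0.006
  k_absorb_portal: 0.03
bile:
  k_bile_c: 9.507053585567734
  i_max: 5.3123125249088075
  c50_ind: 0.010000351145875176
  n_ind: 3.9999388659572284
provenance:
  gut.k_abs: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  bile.k_bile_c: 'scaled: allometric BW^0.75 from monkey'
  bile.i_max: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  bile.c50_ind: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  bile.n_ind: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  tissue.liver.k_out: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  dep: 'calibrated: deposition multiplier'
  tissue.globus_pallidus.k_in: 'scaled: allometric BW^0.75 from monkey'
  tissue.globus_pallidus.k_out: 'scaled: allometric BW^0.75 from monkey'
  tissue.globus_pallidus.k_a: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  tissue.globus_pallidus.k_d: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  tissue.globus_pallidus.b_max: 'calibrated: fit to basal + inhalation tissue-Mn anchors'
  model: 'assumed: 70 kg reference physiology (8/12/2/3/1% volumes; 13 and 20 L/h/kg
    flows)'
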