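# Rhesus monkey, 65 exposure days at 1.5 mg Mn/m3 (6 h/d, 5 d/wk).
species: monkey
schedule:
  air_conc: 1.5
  hours_per_day: 6
  days_per_week: 5
  duration_days: 89
seed: 1
out_dir: results
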