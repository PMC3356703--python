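# Adult human, one year of occupational exposure at the ACGIH TLV.
species: human
schedule:
  air_conc: 0.2          # mg Mn/m3
  hours_per_day: 8
  days_per_week: 5
  duration_days: 365
seed: 1
out_dir: results
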