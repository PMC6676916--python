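# Illustrative, synthetic-compatible screening-model coefficients.
# Hand-set fixture for exercising the scorer; NOT published coefficients.
cutpoint: 0.5
intercept: 1.6
terms:
- aggregation: binary
  category: diagnostic_symptom
  coefficient: -2.4
  name: diagnostic_symptom_365d
  window_days: null
- aggregation: binary
  category: positive_fit_fobt
  coefficient: -3.0
  name: positive_fit_fobt_365d
  window_days: null
- aggregation: binary
  category: iron_deficiency_anemia
  coefficient: -2.2
  name: iron_deficiency_anemia_180d
  window_days: null
- aggregation: binary
  category: polyp_history
  coefficient: -2.6
  name: polyp_history_hx
  window_days: null
- aggregation: binary
  category: ibd_history
  coefficient: -2.0
  name: ibd_history_hx
  window_days: null
- aggregation: binary
  category: crc_history
  coefficient: -2.8
  name: crc_history_hx
  window_days: null
- aggregation: binary
  category: genetic_syndrome
  coefficient: -2.0
  name: genetic_syndrome_hx
  window_days: null
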