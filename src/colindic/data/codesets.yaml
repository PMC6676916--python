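# Illustrative, synthetic-compatible code-set registry.
# These are plausible ICD-9-era codes chosen for the synthetic cohorts;
# they are NOT any published production code list.
categories:
  crc_history:
    entries:
    - code: V10.05
      code_type: ICD9_DX
      finding: hx_crc
    - code: V10.06
      code_type: ICD9_DX
      finding: hx_crc
    - code: C18.9
      code_type: ICDO
      finding: hx_crc
    indication_class: surveillance
    window_days: null
  diagnostic_symptom:
    entries:
    - code: '793.4'
      code_type: ICD9_DX
      finding: abnormal_imaging
    - code: '569.3'
      code_type: ICD9_DX
      finding: rectal_bleeding
    - code: '578'
      code_type: ICD9_DX
      finding: other_gi_bleeding
      prefix: true
    - code: '285.9'
      code_type: ICD9_DX
      finding: other_anemia
    - code: '787.91'
      code_type: ICD9_DX
      finding: diarrhea
    - code: '564.0'
      code_type: ICD9_DX
      finding: constipation
      prefix: true
    - code: '787.99'
      code_type: ICD9_DX
      finding: change_in_bowel_habits
    - code: '564.1'
      code_type: ICD9_DX
      finding: ibs
    - code: '789.3'
      code_type: ICD9_DX
      finding: abdominal_mass
      prefix: true
    - code: '789.0'
      code_type: ICD9_DX
      finding: abdominal_pain
      prefix: true
    - code: '569.42'
      code_type: ICD9_DX
      finding: rectal_pain
    - code: '783.21'
      code_type: ICD9_DX
      finding: weight_loss
    - code: '230.3'
      code_type: ICD9_DX
      finding: suspected_crc
    - code: '555'
      code_type: ICD9_DX
      finding: ibd_active
      prefix: true
    - code: '556'
      code_type: ICD9_DX
      finding: ibd_active
      prefix: true
    - code: '558.9'
      code_type: ICD9_DX
      finding: other_colitis
    indication_class: diagnostic
    window_days: 365
  genetic_syndrome:
    entries:
    - code: V84.09
      code_type: ICD9_DX
      finding: hx_genetic_syndrome
    indication_class: surveillance
    window_days: null
  ibd_history:
    entries:
    - code: V12.79
      code_type: ICD9_DX
      finding: hx_ibd
    indication_class: surveillance
    window_days: null
  incomplete_exam_marker:
    entries:
    - code: V64.3
      code_type: ICD9_DX
    indication_class: null
    window_days: 365
  iron_deficiency_anemia:
    entries:
    - code: '280'
      code_type: ICD9_DX
      finding: iron_deficiency_anemia
      prefix: true
    - code: IDA
      code_type: LAB
      finding: iron_deficiency_anemia
      lab_rule: flag_positive
    - code: HGB
      code_type: LAB
      lab_rule: hgb_low
    - code: FERRITIN
      code_type: LAB
      lab_rule: ferritin
    indication_class: diagnostic
    window_days: 180
  polyp_history:
    entries:
    - code: V12.72
      code_type: ICD9_DX
      finding: hx_polyps
    - code: '211.3'
      code_type: ICD9_DX
      finding: hx_polyps
    indication_class: surveillance
    window_days: null
  positive_fit_fobt:
    entries:
    - code: FIT
      code_type: LAB
      finding: positive_fit_fobt
      lab_rule: flag_positive
    - code: FOBT
      code_type: LAB
      finding: positive_fit_fobt
      lab_rule: flag_positive
    - code: '792.1'
      code_type: ICD9_DX
      finding: positive_fit_fobt
    indication_class: diagnostic
    window_days: 365
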