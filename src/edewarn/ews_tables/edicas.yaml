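# EDICAS — Emergency Department In-hospital Cardiac Arrest Score.
# Item set follows the published score (age, ambulance arrival, SBP, HR,
# BT, RR, SpO2, GCS/acute change).  The per-item point weights in the
# secondary sources available to us are ambiguous, so the weights below
# are package defaults chosen to be clinically defensible; check them
# against the original EDICAS publication before clinical use and
# override this file if they differ.
name: EDICAS
items:
  - variable: age
    name: age_ge_65
    when: {ge: 65}
    points: 1
  - variable: arrival_by_ambulance
    name: arrival_by_ambulance
    when: {eq: 1}
    points: 1
  - variable: SBP
    name: sbp_lt_90
    when: {lt: 90}
    points: 2
  - variable: HR
    name: hr_lt_60_or_gt_90
    when:
      - {lt: 60}
      - {gt: 90}
    points: 1
  - variable: BT
    name: bt_lt_36
    when: {lt: 36}
    points: 1
  - variable: RR
    name: rr_ge_22
    when: {ge: 22}
    points: 1
  - variable: SPO2
    name: spo2_lt_95
    when: {lt: 95}
    points: 2
  - name: gcs_lt_15_or_acute_change
    when:
      - {variable: gcs, lt: 15}
      - {variable: acute_change, eq: 1}
    points: 2
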