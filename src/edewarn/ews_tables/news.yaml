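# NEWS — National Early Warning Score (Royal College of Physicians, 2012).
# Zero-point bands are omitted.  The supplemental-oxygen item (2 points)
# is dropped because the visit schema carries no oxygen-therapy field.
# "Not alert" (AVPU < A, 3 points) is mapped to GCS < 15.
name: NEWS
items:
  - variable: RR
    name: rr_le_8
    when: {le: 8}
    points: 3
  - variable: RR
    name: rr_9_11
    when: {gt: 8, le: 11}
    points: 1
  - variable: RR
    name: rr_21_24
    when: {gt: 20, le: 24}
    points: 2
  - variable: RR
    name: rr_ge_25
    when: {ge: 25}
    points: 3
  - variable: SPO2
    name: spo2_le_91
    when: {le: 91}
    points: 3
  - variable: SPO2
    name: spo2_92_93
    when: {gt: 91, le: 93}
    points: 2
  - variable: SPO2
    name: spo2_94_95
    when: {gt: 93, le: 95}
    points: 1
  - variable: BT
    name: bt_le_35
    when: {le: 35}
    points: 3
  - variable: BT
    name: bt_35_1_36
    when: {gt: 35, le: 36}
    points: 1
  - variable: BT
    name: bt_38_1_39
    when: {gt: 38, le: 39}
    points: 1
  - variable: BT
    name: bt_ge_39_1
    when: {gt: 39}
    points: 2
  - variable: SBP
    name: sbp_le_90
    when: {le: 90}
    points: 3
  - variable: SBP
    name: sbp_91_100
    when: {gt: 90, le: 100}
    points: 2
  - variable: SBP
    name: sbp_101_110
    when: {gt: 100, le: 110}
    points: 1
  - variable: SBP
    name: sbp_ge_220
    when: {ge: 220}
    points: 3
  - variable: HR
    name: hr_le_40
    when: {le: 40}
    points: 3
  - variable: HR
    name: hr_41_50
    when: {gt: 40, le: 50}
    points: 1
  - variable: HR
    name: hr_91_110
    when: {gt: 90, le: 110}
    points: 1
  - variable: HR
    name: hr_111_130
    when: {gt: 110, le: 130}
    points: 2
  - variable: HR
    name: hr_ge_131
    when: {gt: 130}
    points: 3
  - variable: gcs
    name: not_alert
    when: {lt: 15}
    points: 3
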