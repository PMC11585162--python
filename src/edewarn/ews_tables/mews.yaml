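# MEWS — Modified Early Warning Score (Subbe et al., QJM 2001).
# Zero-point bands are omitted (no item = 0 points).  The AVPU item is
# mapped onto the Glasgow Coma Scale because the schema records GCS:
# 15 = alert (0), 14 = voice (1), 9-13 = pain (2), <=8 = unresponsive (3).
name: MEWS
items:
  - variable: SBP
    name: sbp_le_70
    when: {le: 70}
    points: 3
  - variable: SBP
    name: sbp_71_80
    when: {gt: 70, le: 80}
    points: 2
  - variable: SBP
    name: sbp_81_100
    when: {gt: 80, le: 100}
    points: 1
  - variable: SBP
    name: sbp_ge_200
    when: {ge: 200}
    points: 2
  - variable: HR
    name: hr_lt_40
    when: {lt: 40}
    points: 2
  - variable: HR
    name: hr_40_50
    when: {ge: 40, le: 50}
    points: 1
  - variable: HR
    name: hr_101_110
    when: {gt: 100, le: 110}
    points: 1
  - variable: HR
    name: hr_111_129
    when: {gt: 110, lt: 130}
    points: 2
  - variable: HR
    name: hr_ge_130
    when: {ge: 130}
    points: 3
  - variable: RR
    name: rr_lt_9
    when: {lt: 9}
    points: 2
  - variable: RR
    name: rr_15_20
    when: {gt: 14, le: 20}
    points: 1
  - variable: RR
    name: rr_21_29
    when: {gt: 20, lt: 30}
    points: 2
  - variable: RR
    name: rr_ge_30
    when: {ge: 30}
    points: 3
  - variable: BT
    name: bt_lt_35
    when: {lt: 35}
    points: 2
  - variable: BT
    name: bt_ge_38_5
    when: {ge: 38.5}
    points: 2
  - variable: gcs
    name: avpu_voice
    when: {eq: 14}
    points: 1
  - variable: gcs
    name: avpu_pain
    when: {ge: 9, le: 13}
    points: 2
  - variable: gcs
    name: avpu_unresponsive
    when: {le: 8}
    points: 3
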