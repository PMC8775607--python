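setup_spec:
  kind: triangular
  params:
  - 1.0
  - 5.0
  - 9.0
rooms:
- room_id: 5
  tech_sex: female
- room_id: 6
  tech_sex: male
- room_id: 7
  tech_sex: female
- room_id: 8
  tech_sex: male
- room_id: 9
  tech_sex: female
- room_id: 10
  tech_sex: male
exams:
- name: liver
  slot_rule: fixed40
  sex_constraint: none
  service_spec:
    kind: triangular
    params:
    - 22.0
    - 30.0
    - 38.0
- name: dvt
  slot_rule: dvt_split
  sex_constraint: same_sex_tech
  service_spec:
    kind: mixture
    components:
    - weight: 0.7
      kind: triangular
      params:
      - 8.0
      - 15.0
      - 22.0
    - weight: 0.3
      kind: triangular
      params:
      - 22.0
      - 30.0
      - 38.0
- name: prostate
  slot_rule: fixed20
  sex_constraint: male_tech_only
  service_spec:
    kind: mixture
    components:
    - weight: 0.485
      kind: beta_scaled
      params:
      - 3.0
      - 7.0
      - 1.9
      - 1.16
    - weight: 0.424
      kind: weibull_scaled
      params:
      - 10.0
      - 3.46
      - 1.23
    - weight: 0.091
      kind: weibull_scaled
      params:
      - 20.0
      - 6.99
      - 1.29
- name: scrotum
  slot_rule: fixed20
  sex_constraint: male_tech_only
  service_spec:
    kind: triangular
    params:
    - 7.0
    - 15.0
    - 23.0
- name: abdomen
  slot_rule: fixed20
  sex_constraint: none
  service_spec:
    kind: triangular
    params:
    - 7.0
    - 15.0
    - 23.0
- name: shoulder
  slot_rule: fixed20
  sex_constraint: none
  service_spec:
    kind: triangular
    params:
    - 8.35
    - 16.35
    - 24.35
- name: other
  slot_rule: fixed20
  sex_constraint: none
  service_spec:
    kind: triangular
    params:
    - 7.0
    - 15.0
    - 23.0
classes:
- name: outpatient
  share: 0.7245275472452755
  arrival_model: renewal_process
  interval_minutes: null
  batch_size: 1
  interarrival_spec:
    kind: exponential
    params:
    - 6.295524908528005
  male_probability: 0.5
  dvt_male_probability: 0.42857142857142855
  exam_mix:
  - - abdomen
    - 0.38
  - - liver
    - 0.12
  - - dvt
    - 0.08
  - - prostate
    - 0.03
  - - scrotum
    - 0.02
  - - shoulder
    - 0.07
  - - other
    - 0.3
- name: inpatient
  share: 0.19978002199780023
  arrival_model: renewal_process
  interval_minutes: null
  batch_size: 1
  interarrival_spec:
    kind: exponential
    params:
    - 24.05161290322581
  male_probability: 0.5
  dvt_male_probability: 0.42857142857142855
  exam_mix:
  - - abdomen
    - 0.38
  - - liver
    - 0.12
  - - dvt
    - 0.08
  - - prostate
    - 0.03
  - - scrotum
    - 0.02
  - - shoulder
    - 0.07
  - - other
    - 0.3
- name: emergency
  share: 0.0756924307569243
  arrival_model: renewal_process
  interval_minutes: null
  batch_size: 1
  interarrival_spec:
    kind: exponential
    params:
    - 59.01846965699209
  male_probability: 0.5
  dvt_male_probability: 0.42857142857142855
  exam_mix:
  - - abdomen
    - 0.38
  - - liver
    - 0.12
  - - dvt
    - 0.08
  - - prostate
    - 0.03
  - - scrotum
    - 0.02
  - - shoulder
    - 0.07
  - - other
    - 0.3
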