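attributes:
- name: amount
  levels:
  - 50
  - 100
  - 200
  - 350
  - 500
  - 750
  - 1000
  coding: continuous
  preference_direction:
  - 50
  - 100
  - 200
  - 350
  - 500
  - 750
  - 1000
- name: incentive_type
  levels:
  - voucher
  - cash
  coding: effects
  omitted_level: voucher
  preference_direction:
  - voucher
  - cash
- name: schedule
  levels:
  - escalating
  - consistent
  coding: effects
  omitted_level: escalating
  preference_direction:
  - escalating
  - consistent
- name: sessions
  levels:
  - 1/fortnight
  - 1/week
  - 2/week
  - 3/week
  coding: effects
  omitted_level: 3/week
  preference_direction:
  - 3/week
  - 2/week
  - 1/fortnight
  - 1/week
- name: location
  levels:
  - workplace
  - healthcare
  coding: effects
  omitted_level: workplace
  preference_direction:
  - workplace
  - healthcare
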