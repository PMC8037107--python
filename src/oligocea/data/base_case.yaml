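settings:
  age_start: 73
  age_max: 100
  discount_rate: 0.03
  wtp: 100000.0
  cost_per_hospital_day: 2424.0
  cost_no_recurrence_per_cycle: 855.0
  cost_recurrence_per_cycle: 3935.0
  utility_no_recurrence: 1.0
  utility_hepatic_recurrence: 0.65
  utility_other_recurrence: 0.19
  utility_death: 0.0
  p_death_hepatic_recurrence: 0.12
  p_death_other_recurrence: 0.05
  p_success_second_session: 1.0
  recurrence_mortality_compounds_background: false
  first_cycle_utility: full_year
  half_cycle_correction: true
strategies:
- name: surgery
  p_success_first: 0.99
  acute_procedure_cost: 2421.0
  hospital_days: 7
  qol_first_month: 0.7
  mortality_year1: 0.0825
  p_hepatic_recurrence: 0.025
  p_other_recurrence: 0.05
- name: RFA
  p_success_first: 0.93
  acute_procedure_cost: 1493.0
  hospital_days: 4
  qol_first_month: 0.95
  mortality_year1: 0.06
  p_hepatic_recurrence: 0.077
  p_other_recurrence: 0.05
- name: MWA
  p_success_first: 0.97
  acute_procedure_cost: 1493.0
  hospital_days: 4
  qol_first_month: 0.95
  mortality_year1: 0.055
  p_hepatic_recurrence: 0.04
  p_other_recurrence: 0.05
lifetable_source: synthetic_us2014_lifetable.csv
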