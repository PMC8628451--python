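# ICU CRBSI early-detection case.
# Illustrative reconstruction: four-state structure and all parameter
# values are package assumptions unless printed in the main-text results.
#
# Per arm, a decision tree splits the entering patient on CRBSI
# occurrence (p_crbsi). Infected patients incur extra ICU days (a tree
# payoff cost) and attributable ICU mortality (a shift of the Markov
# entry distribution toward dead); early detection reduces both. The
# technology is priced per bed per year and spread over the bed's annual
# patient throughput. Weekly cycles resolve the short ICU/ward phase.

name: crbsi
cycle_plan:
  horizon_years: 40            # lifetime proxy for discharged survivors
  cycle_length_years: 0.019230769230769232  # 1 week
  discount_rate_costs: 0.03
  discount_rate_effects: 0.03
  half_cycle_correction: true

states:
  - {name: icu}
  - {name: ward}               # post-ICU hospital stay
  - {name: discharged}
  - {name: dead, absorbing: true}

shared: &shared
  transitions:
    - {from: icu, to: ward, value: p_icu_to_ward}
    - {from: icu, to: dead, value: p_icu_death}
    - {from: ward, to: discharged, value: p_ward_discharge}
    - {from: ward, to: dead, value: p_ward_death}
    - {from: discharged, to: dead, value: p_bg_death}
  state_costs:
    icu: {product: [c_icu_day, 7.024038461538462]}    # days per weekly cycle
    ward: {product: [c_ward_day, 7.024038461538462]}
    discharged: c_followup_cycle
  state_utilities:
    icu: u_icu
    ward: u_ward
    discharged: u_discharged

arms:
  comparator:
    <<: *shared
    upfront_cost: 0.0
    tree:
      label: crbsi_late
      branches:
        - probability: p_crbsi
          cost:
            sum:
              - {product: [los_extra_late, c_icu_day]}
              - c_antibiotics
          terminal:
            dead: p_mort_late
            icu: {complement: p_mort_late}
        - probability: {complement: p_crbsi}
          cost: 0.0
          terminal: {icu: 1.0}

  intervention:
    <<: *shared
    upfront_cost: {ratio: [price_per_bed, patients_per_bed]}
    tree:
      label: crbsi_early
      branches:
        - probability: p_crbsi
          cost:
            sum:
              - {product: [los_extra_early, c_icu_day]}
              - c_antibiotics
          terminal:
            dead: p_mort_early
            icu: {complement: p_mort_early}
        - probability: {complement: p_crbsi}
          cost: 0.0
          terminal: {icu: 1.0}
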