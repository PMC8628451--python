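# CLL watch-and-wait stratification case.
# Illustrative reconstruction: the four-state structure and all bindings
# not printed in the main-text results table are package assumptions.
#
# Intervention: analytics + genomic/genetic testing at entry flags a
# high-risk fraction (f_highrisk) who receive early ibrutinib while in
# watch-and-wait; their per-cycle probability of needing the next
# treatment line is hazard-ratio adjusted (hr_ttt). Everyone else follows
# current care. Only the watch_wait row and its payoffs differ between
# arms, so a null intervention (hr=1, zero cost deltas, equal utility)
# leaves the arms identical.

name: cll
cycle_plan:
  horizon_years: 40            # lifetime proxy; cohort is effectively extinct by then
  cycle_length_years: 0.08333333333333333   # 1 month
  discount_rate_costs: 0.03
  discount_rate_effects: 0.03
  half_cycle_correction: true

states:
  - {name: watch_wait}
  - {name: treatment}          # next treatment line (venetoclax-based)
  - {name: subsequent}         # relapse / later-line palliation
  - {name: dead, absorbing: true}

arms:
  comparator:
    entry: {watch_wait: 1.0}
    upfront_cost: 0.0
    transitions:
      - {from: watch_wait, to: treatment, value: p_next_treatment}
      - {from: watch_wait, to: dead, value: p_death_ww}
      - {from: treatment, to: subsequent, value: p_progress_tx}
      - {from: treatment, to: dead, value: p_death_tx}
      - {from: subsequent, to: dead, value: p_death_subsequent}
    state_costs:
      watch_wait: c_monitoring
      treatment: c_venetoclax_cycle
      subsequent: c_palliative_cycle
    state_utilities:
      watch_wait: u_ww
      treatment: u_tx
      subsequent: u_subsequent

  intervention:
    entry: {watch_wait: 1.0}
    upfront_cost: c_analytics_testing
    transitions:
      - from: watch_wait
        to: treatment
        value:
          lerp:
            - p_next_treatment
            - {hr_adjust: [p_next_treatment, hr_ttt]}
            - f_highrisk
      - {from: watch_wait, to: dead, value: p_death_ww}
      - {from: treatment, to: subsequent, value: p_progress_tx}
      - {from: treatment, to: dead, value: p_death_tx}
      - {from: subsequent, to: dead, value: p_death_subsequent}
    state_costs:
      watch_wait:
        sum:
          - c_monitoring
          - {product: [f_highrisk, c_ibrutinib_cycle]}
      treatment: c_venetoclax_cycle
      subsequent: c_palliative_cycle
    state_utilities:
      watch_wait: {lerp: [u_ww, u_early, f_highrisk]}
      treatment: u_tx
      subsequent: u_subsequent
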