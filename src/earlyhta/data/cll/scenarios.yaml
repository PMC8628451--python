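# Named scenario override maps for the CLL case.
# best_case mirrors the published best-case footnote: low hazard ratio
# for time to next treatment with early ibrutinib (0.11), 50%-reduced
# per-cycle drug prices, low analytics+testing cost, high early-treatment
# utility.
# null_intervention makes the intervention arm structurally identical to
# current care (hazard ratio 1, zero analytics and early-drug cost,
# early-treatment utility equal to watch-and-wait utility 0.80 — keep in
# sync with u_ww if the base table changes).
best_case:
  hr_ttt: 0.11
  c_ibrutinib_cycle: 2542
  c_venetoclax_cycle: 2731
  c_analytics_testing: 100
  u_early: 0.78
null_intervention:
  hr_ttt: 1.0
  c_ibrutinib_cycle: 0.0
  c_analytics_testing: 0.0
  u_early: 0.80
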