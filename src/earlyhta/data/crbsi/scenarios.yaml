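# Named scenario override maps for the CRBSI case.
# null_intervention removes every difference between the arms: early
# detection has the same mortality and length-of-stay consequences as
# late detection and the technology is free (values mirror the late-arm
# base values in parameters.csv — keep in sync if that table changes).
# free_technology keeps the clinical effect but zeroes the price, giving
# the savings term N of the headroom formula per patient.
null_intervention:
  p_mort_early: 0.25
  los_extra_early: 10
  price_per_bed: 0.0
free_technology:
  price_per_bed: 0.0
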