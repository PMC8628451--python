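name,kind,base,low,high,dist_family,dist_arg1,dist_arg2,dist_arg3,source_tag
p_next_treatment,probability,0.010,0.005,0.020,,,,,assumption
p_death_ww,probability,0.0017,0.0008,0.0034,,,,,assumption
p_progress_tx,probability,0.012,0.006,0.024,,,,,assumption
p_death_tx,probability,0.003,0.0015,0.006,,,,,assumption
p_death_subsequent,probability,0.020,0.010,0.040,,,,,assumption
u_ww,utility,0.80,0.70,0.90,,,,,literature
u_tx,utility,0.74,0.65,0.83,,,,,assumption
u_subsequent,utility,0.60,0.50,0.70,,,,,assumption
u_early,utility,0.71,0.60,0.78,,,,,assumption
c_monitoring,cost,150,75,300,,,,,assumption
c_ibrutinib_cycle,cost,5084,2542,7626,,,,,literature
c_venetoclax_cycle,cost,5462,2731,8193,,,,,literature
c_palliative_cycle,cost,1500,750,3000,,,,,assumption
c_analytics_testing,cost,1000,100,2000,,,,,assumption
f_highrisk,probability,0.35,0.20,0.50,,,,,assumption
hr_ttt,hazard-ratio,0.60,0.11,1.00,,,,,literature
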