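name,kind,base,low,high,dist_family,dist_arg1,dist_arg2,dist_arg3,source_tag
p_crbsi,probability,0.10,0.02,0.30,,,,,literature
p_mort_late,probability,0.25,0.15,0.35,,,,,literature
p_mort_early,probability,0.20,0.12,0.30,,,,,literature
los_extra_late,count,10,5,15,,,,,literature
los_extra_early,count,6,3,9,,,,,literature
c_icu_day,cost,1500,1000,2500,,,,,guideline
c_ward_day,cost,400,250,600,,,,,guideline
c_followup_cycle,cost,10,5,20,,,,,assumption
c_antibiotics,cost,400,200,800,,,,,guideline
price_per_bed,cost,10000,0,40000,,,,,assumption
patients_per_bed,count,20,10,30,,,,,assumption
p_icu_to_ward,probability,0.45,0.30,0.60,,,,,assumption
p_icu_death,probability,0.02,0.01,0.05,,,,,literature
p_ward_discharge,probability,0.35,0.20,0.50,,,,,assumption
p_ward_death,probability,0.005,0.002,0.010,,,,,assumption
p_bg_death,probability,0.0004,0.0002,0.0008,,,,,assumption
u_icu,utility,0.40,0.30,0.50,,,,,literature
u_ward,utility,0.60,0.50,0.70,,,,,assumption
u_discharged,utility,0.75,0.65,0.85,,,,,assumption
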