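# Base-case run settings: 6-month cycles, 15-year horizon, 5% annual
# discounting of costs and QALYs, start age 40, 50% female cohort.
cycle_length: 0.5
horizon: 15.0
discount_rate_costs: 0.05
discount_rate_qalys: 0.05
start_age: 40.0
sex_mix: 0.5
half_cycle_correction: true
wtp_threshold: 50000.0
discount_compounding: annual
event_discount_timing: start
utility_subgroup: all
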