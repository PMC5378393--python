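analyte,unit,basal_mean,basal_sem,low_mg_mean,low_mg_sem,printed_pct_change,printed_direction
Mg,mg/day,0.49,0.05,0.02,0.00,96,decrease
Ca,mg/day,0.14,0.02,0.04,0.01,71,decrease
P,mg/day,3.92,0.16,4.11,0.16,,increase
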