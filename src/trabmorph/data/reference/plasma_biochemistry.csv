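analyte,unit,basal_mean,basal_sem,low_mg_mean,low_mg_sem,printed_pct_change,printed_direction
Mg,mg/dL,2.27,0.03,1.29,0.04,43,decrease
Ca,mg/dL,7.73,0.57,4.66,0.11,39,decrease
P,mg/dL,5.89,0.27,5.36,0.29,,similar
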