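variable,unit,basal_mean,basal_sem,low_mg_mean,low_mg_sem,printed_pct_change,printed_direction
total_tissue_volume,mm^3,3.68,0.06,3.48,0.09,5.30,decrease
bone_volume,mm^3,0.36,0.04,0.26,0.02,27.69,decrease
percent_bone_volume,%,9.75,1.17,7.51,0.59,22.93,decrease
fractal_dimension,,2.11,0.02,2.02,0.01,4.27,decrease
structure_model_index,,2.38,0.05,2.61,0.04,9.65,increase
segment_count,,1119,225,794,73,29.03,decrease
segment_density,mm^-3,5507,560,4490,176,18.47,decrease
mean_segment_radius,mm,0.0140,0.0002,0.0139,0.0003,,similar
mean_segment_length,mm,0.1355,0.0021,0.1359,0.0022,,similar
node_count,,704,127,508,39,27.85,decrease
node_density,mm^-3,3530,372,2897,140,17.93,decrease
sa_to_v,mm^-1,80.39,4.43,85.88,1.73,6.83,increase
bmd,mg-HA/cm^3,40.07,4.55,33.10,2.80,17.38,decrease
bmc,mg-HA,149.01,19.09,115.74,10.49,22.33,decrease
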