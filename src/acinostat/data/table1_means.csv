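quantity,value
body_weight_g,295.82
lung_volume_ml,7.51
rul_wd_ml,0.821
rml_wd_ml,0.938
rml_cavalieri_paraffin_ml,0.643
rml_cavalieri_cpd_ml,0.364
rml_shrinkage_paraffin_pct,28.70
rml_shrinkage_cpd_pct,61.97
rll_wd_ml,2.14
lc_wd_ml,0.954
ll_wd_ml,2.66
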