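lobe,mean_acinar_volume_ul,mav_sd_ul,ttest_vs_rml_p,counted_mean,counted_sd,estimated_mean,estimated_sd,counted_vs_estimated_p,matching_pct_mean,matching_pct_sd,n_counted_animals
RUL,1.06,0.018,0.109,689,138,668,126,0.144,97.09,1.84,3
RML,1.16,0.138,,686,89,,,,,,8
RLL,0.96,0.066,0.117,1808,103,1689,77,0.201,93.59,5.64,3
LC,1.24,0.123,0.211,734,66,780,80,0.215,106.33,6.36,3
LL,1.22,0.095,0.278,1973,192,2095,153,0.275,106.49,7.89,3
whole_lung,1.11,0.044,0.978,5943,521,5971,388,0.869,100.80,5.16,3
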