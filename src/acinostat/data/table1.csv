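sample,body_weight_g,lung_volume_ml,rul_wd_ml,rml_wd_ml,rml_cavalieri_ml,rml_shrinkage_pct,rll_wd_ml,lc_wd_ml,ll_wd_ml,embedding
A,291.00,7.03,0.727,0.824,0.591,28.23,2.02,0.862,2.59,paraffin
B,315.20,7.43,0.767,0.836,0.590,29.40,2.24,0.860,2.73,paraffin
C,306.80,7.44,0.737,1.04,0.747,28.47,2.07,0.989,2.60,paraffin
D,280.95,7.02,0.740,0.985,0.388,60.61,1.97,0.847,2.49,cpd
E,316.25,8.07,0.997,1.04,0.393,62.19,2.14,1.07,2.83,cpd
F,294.93,6.82,0.731,0.80,0.316,60.53,1.95,0.912,2.43,cpd
G,294.05,8.15,0.903,0.924,0.348,62.34,2.43,1.01,2.87,cpd
H,267.41,8.14,0.964,1.05,0.377,64.20,2.30,1.09,2.73,cpd
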