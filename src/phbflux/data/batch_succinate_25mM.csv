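time_h,dry_weight_g_per_L,dry_weight_g_per_L_sd,phb_mg_per_g,phb_mg_per_g_sd,succinate_mM,succinate_mM_sd
0,0.04,0.000,0.0,0.0,25.0,0.0
0.5,0.04,0.00,78.4,8.4,24.9,0.0
2,0.06,0.01,74.6,9.1,23.7,0.3
4,0.07,0.01,75.0,8.3,23.2,0.9
7,0.21,0.03,66.7,2.7,20.3,0.5
10,0.59,0.07,72.3,1.4,15.7,0.6
12,0.82,0.03,68.9,5.4,9.1,0.3
14,1.01,0.01,72.4,5.4,4.7,0.5
16,1.12,0.03,73.6,9.3,0.9,0.2
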