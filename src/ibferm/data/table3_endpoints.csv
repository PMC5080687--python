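label,duration_h,ph_control,consumed_glucose_g_per_L,consumed_glycerol_g_per_L,product_butanol_g_per_L,product_isopropanol_g_per_L,product_acetone_g_per_L,product_acetic_acid_g_per_L,product_butyric_acid_g_per_L
22:0,28,none,21.85,0,4.33,2.44,0.28,0.51,0.69
20:2,28,none,19.85,1.83,4.66,2.24,0.18,0.46,0.73
18:4,28,none,17.62,3.59,5.04,2.07,0,0.43,0.59
14:8,28,none,13.35,7.01,5.38,1.57,0,0.24,0.98
9:13,25,none,8.98,10.94,5.09,0.83,0,0.11,1.95
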