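label,duration_h,ph_control,consumed_glucose_g_per_L,consumed_mannose_g_per_L,consumed_fructose_g_per_L,consumed_galactose_g_per_L,consumed_xylose_g_per_L,consumed_arabinose_g_per_L,consumed_cellobiose_g_per_L,consumed_sucrose_g_per_L,consumed_glycerol_g_per_L,product_butanol_g_per_L,product_isopropanol_g_per_L,product_acetone_g_per_L,product_acetic_acid_g_per_L,product_butyric_acid_g_per_L,product_pdo_13_g_per_L
glucose,28,none,21.62,0,0,0,0,0,0,0,0,4.49,2.48,0.33,0.43,0.72,0
mannose,28,none,0,19.92,0,0,0,0,0,0,0,4.40,1.88,0.33,0.66,0.93,0
fructose,28,none,0,0,21.63,0,0,0,0,0,0,4.38,1.63,0.19,0.85,1.49,0
galactose,28,none,0,0,0,5.96,0,0,0,0,0,0.59,0,0,0.44,1.90,0
xylose,28,none,0,0,0,0,12.81,0,0,0,0,0.87,0,0,0.68,4.71,0
arabinose,28,none,0,0,0,0,0,8.24,0,0,0,0,0,0,0.15,4.20,0
cellobiose,28,none,0,0,0,0,0,0,20.02,0,0,4.50,2.65,0.45,0.43,0.24,0
sucrose,36,none,0,0,0,0,0,0,0,18.20,0,5.01,1.71,0.34,0.97,0.87,0
glycerol,28,none,0,0,0,0,0,0,0,0,18.13,3.91,0,0,0.27,2.20,3.40
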