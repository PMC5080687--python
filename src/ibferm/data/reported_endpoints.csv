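label,duration_h,ph_control,consumed_glucose_g_per_L,consumed_glycerol_g_per_L,product_butanol_g_per_L,product_isopropanol_g_per_L
glucose_16h,16,none,21.62,0,4.41,2.35
glucose_41,28,none,41.02,0,8.60,3.68
ph55,32,5.5,46.35,0,9.43,4.49
crude_14_8,24,none,23.04,12.64,9.86,2.88
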