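species,slope,intercept
K_fortunei,0.4158,41.3318
P_armandii,0.5856,18.7435
P_yunnanensis,0.5101,1.0451
C_funebris,0.6129,46.1451
Quercus_sp,1.1453,8.5473
E_robusta,0.8873,4.5539
A_cremastogyne,1.0687,10.2370
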