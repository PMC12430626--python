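species,stratum,bef,root_shoot,wood_density,carbon_fraction
K_fortunei,young,1.667,0.277,0.448,0.500
K_fortunei,middle_aged,2.300,0.302,0.448,0.500
K_fortunei,near_mature,1.382,0.274,0.448,0.500
K_fortunei,mature,1.459,0.238,0.448,0.500
K_fortunei,total,1.347,0.195,0.448,0.500
P_armandii,young,1.785,0.170,0.396,0.523
P_armandii,middle_aged,1.808,0.162,0.396,0.523
P_armandii,near_mature,1.830,0.182,0.396,0.523
P_armandii,mature,1.679,0.171,0.396,0.523
P_armandii,total,1.717,0.174,0.396,0.523
P_yunnanensis,young,1.619,0.146,0.483,0.511
P_yunnanensis,middle_aged,1.837,0.143,0.483,0.511
P_yunnanensis,near_mature,1.333,0.238,0.483,0.511
P_yunnanensis,mature,1.585,0.190,0.483,0.511
P_yunnanensis,total,1.585,0.202,0.483,0.511
C_funebris,young,1.732,0.220,0.478,0.510
C_funebris,middle_aged,1.847,0.218,0.478,0.510
C_funebris,near_mature,1.497,0.233,0.478,0.510
C_funebris,mature,1.233,0.329,0.478,0.510
C_funebris,total,1.535,0.365,0.478,0.510
Quercus_sp,young,1.355,0.292,0.676,0.500
Quercus_sp,middle_aged,1.380,0.260,0.676,0.500
Quercus_sp,near_mature,1.327,0.275,0.676,0.500
Quercus_sp,mature,1.360,0.410,0.676,0.500
Quercus_sp,total,1.587,0.153,0.676,0.500
E_robusta,young,1.263,0.221,0.578,0.525
E_robusta,middle_aged,1.297,0.219,0.578,0.525
E_robusta,near_mature,1.178,0.221,0.578,0.525
E_robusta,mature,1.165,0.181,0.578,0.525
E_robusta,total,1.151,0.226,0.578,0.525
A_cremastogyne,young,1.424,0.248,0.541,0.491
A_cremastogyne,middle_aged,1.526,0.229,0.541,0.491
A_cremastogyne,near_mature,1.395,0.279,0.541,0.491
A_cremastogyne,mature,1.252,0.235,0.541,0.491
A_cremastogyne,total,1.180,0.212,0.541,0.491
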