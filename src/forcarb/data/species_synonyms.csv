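token,species
k fortunei,K_fortunei
keteleeria fortunei,K_fortunei
keteleeria,K_fortunei
p armandii,P_armandii
pinus armandii,P_armandii
armand pine,P_armandii
p yunnanensis,P_yunnanensis
pinus yunnanensis,P_yunnanensis
yunnan pine,P_yunnanensis
c funebris,C_funebris
cupressus funebris,C_funebris
quercus,Quercus_sp
quercus sp,Quercus_sp
quercus spp,Quercus_sp
oak,Quercus_sp
e robusta,E_robusta
eucalyptus robusta,E_robusta
eucalyptus,E_robusta
a cremastogyne,A_cremastogyne
alnus cremastogyne,A_cremastogyne
alder,A_cremastogyne
economic,economic_mixed
economic mixed,economic_mixed
economic forest,economic_mixed
orchard,economic_mixed
shrub,shrub_mixed
shrub mixed,shrub_mixed
shrubland,shrub_mixed
shrub forest,shrub_mixed
none,none
bare,none
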