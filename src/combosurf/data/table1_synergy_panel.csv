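cell_line,meaning,blending_synergy,combination_index,incubation_h,fab
TF-1a,Synergy,36.5,0.3,72,M6
TF-1a/Ara-C,Synergy,34.9,NA,72,M6
NB4,Synergy,33.5,NA,120,M3
Kasumi-1,Synergy,31.8,0.45,120,M2
MOLM-16,Synergy,28.4,NA,120,M7
HL-60/MX2,Synergy,23.3,0.42,120,M2
HL-60,Synergy,19.6,0.41,120,M2
HEL92.1.7,Additivity,14.6,NA,72,M6
OCI-M2,Additivity,10.9,0.81,72,M1
GF-D8,Additivity,8.6,NA,168,M7
CMK-11-5,Additivity,4.3,0.96,72,M5
THP-1,Additivity,-5.5,NA,144,M4
OCI-AML3,Additivity,-7.9,NA,168,M4
EOL-1,Additivity,-17.3,NA,120,Eosinophilic
CMK-86,Subadditivity,-27.6,1.73,72,M7
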