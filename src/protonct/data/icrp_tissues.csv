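name,density,rho_e,z_eff,z_eff_unc,composition
adipose,0.95,,,,H:0.114 C:0.598 N:0.007 O:0.278 Na:0.001 S:0.001 Cl:0.001
blood,1.06,,,,H:0.102 C:0.110 N:0.033 O:0.745 Na:0.001 P:0.001 S:0.002 Cl:0.003 K:0.002 Fe:0.001
brain,1.04,,,,H:0.107 C:0.145 N:0.022 O:0.712 Na:0.002 P:0.004 S:0.002 Cl:0.003 K:0.003
breast,1.02,,,,H:0.106 C:0.332 N:0.030 O:0.527 Na:0.001 P:0.001 S:0.002 Cl:0.001
cartilage,1.10,,,,H:0.096 C:0.099 N:0.022 O:0.744 Na:0.005 P:0.022 S:0.009 Cl:0.003
cortical_bone,1.92,,,,H:0.034 C:0.155 N:0.042 O:0.435 Na:0.001 Mg:0.002 P:0.103 S:0.003 Ca:0.225
eye_lens,1.07,,,,H:0.096 C:0.195 N:0.057 O:0.646 Na:0.001 P:0.001 S:0.003 Cl:0.001
gi_tract,1.03,,,,H:0.106 C:0.115 N:0.022 O:0.751 Na:0.001 P:0.001 S:0.001 Cl:0.002 K:0.001
heart,1.05,,,,H:0.104 C:0.139 N:0.029 O:0.718 Na:0.001 P:0.002 S:0.002 Cl:0.002 K:0.003
kidney,1.05,,,,H:0.103 C:0.132 N:0.030 O:0.724 Na:0.002 P:0.002 S:0.002 Cl:0.002 K:0.002 Ca:0.001
liver,1.06,,,,H:0.102 C:0.139 N:0.030 O:0.716 Na:0.002 P:0.003 S:0.003 Cl:0.002 K:0.003
lung_inflated,0.26,,,,H:0.103 C:0.105 N:0.031 O:0.749 Na:0.002 P:0.002 S:0.003 Cl:0.003 K:0.002
muscle_skeletal,1.05,,,,H:0.102 C:0.143 N:0.034 O:0.710 Na:0.001 P:0.002 S:0.003 Cl:0.001 K:0.004
ovary,1.05,,,,H:0.105 C:0.093 N:0.024 O:0.768 Na:0.002 P:0.002 S:0.002 Cl:0.002 K:0.002
pancreas,1.04,,,,H:0.106 C:0.169 N:0.022 O:0.694 Na:0.002 P:0.002 S:0.001 Cl:0.002 K:0.002
red_marrow,1.03,,,,H:0.105 C:0.414 N:0.034 O:0.439 P:0.001 S:0.002 Cl:0.002 K:0.002 Fe:0.001
yellow_marrow,0.98,,,,H:0.115 C:0.644 N:0.007 O:0.231 Na:0.001 S:0.001 Cl:0.001
skin,1.09,,,,H:0.100 C:0.204 N:0.042 O:0.645 Na:0.002 P:0.001 S:0.002 Cl:0.003 K:0.001
spleen,1.06,,,,H:0.103 C:0.113 N:0.032 O:0.741 Na:0.001 P:0.003 S:0.002 Cl:0.002 K:0.003
stomach,1.05,,,,H:0.104 C:0.139 N:0.029 O:0.721 Na:0.001 P:0.001 S:0.002 Cl:0.001 K:0.002
testis,1.04,,,,H:0.106 C:0.099 N:0.020 O:0.766 Na:0.002 P:0.001 S:0.002 Cl:0.002 K:0.002
thyroid,1.05,,,,H:0.104 C:0.119 N:0.024 O:0.745 Na:0.002 P:0.001 S:0.001 Cl:0.002 K:0.001 I:0.001
urinary_bladder,1.04,,,,H:0.105 C:0.096 N:0.026 O:0.761 Na:0.002 P:0.002 S:0.002 Cl:0.003 K:0.003
spongiosa,1.18,,,,H:0.085 C:0.404 N:0.028 O:0.367 Na:0.001 Mg:0.001 P:0.034 S:0.002 Cl:0.002 K:0.001 Ca:0.074 Fe:0.001
cranium,1.61,,,,H:0.050 C:0.212 N:0.040 O:0.435 Na:0.001 Mg:0.002 P:0.081 S:0.003 Ca:0.176
femur,1.33,,,,H:0.070 C:0.345 N:0.028 O:0.368 Na:0.001 Mg:0.001 P:0.055 S:0.002 Ca:0.129 Fe:0.001
humerus,1.46,,,,H:0.060 C:0.314 N:0.031 O:0.369 Na:0.001 Mg:0.001 P:0.070 S:0.002 Ca:0.152
mandible,1.68,,,,H:0.046 C:0.199 N:0.041 O:0.435 Na:0.001 Mg:0.002 P:0.086 S:0.003 Ca:0.187
ribs_2_6,1.41,,,,H:0.064 C:0.263 N:0.039 O:0.436 Na:0.001 Mg:0.001 P:0.060 S:0.003 Cl:0.001 K:0.001 Ca:0.131
ribs_10,1.52,,,,H:0.056 C:0.235 N:0.040 O:0.434 Na:0.001 Mg:0.001 P:0.072 S:0.003 Cl:0.001 K:0.001 Ca:0.156
sacrum,1.29,,,,H:0.074 C:0.302 N:0.037 O:0.438 Mg:0.001 P:0.045 S:0.002 Cl:0.001 K:0.001 Ca:0.098
vertebra_c4,1.42,,,,H:0.063 C:0.261 N:0.039 O:0.436 Na:0.001 Mg:0.001 P:0.061 S:0.003 Cl:0.001 K:0.001 Ca:0.133
vertebra_d6_l3,1.33,,,,H:0.070 C:0.287 N:0.038 O:0.437 Na:0.001 Mg:0.001 P:0.051 S:0.002 Cl:0.001 K:0.001 Ca:0.111
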