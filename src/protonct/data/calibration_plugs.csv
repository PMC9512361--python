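name,density,rho_e,z_eff,z_eff_unc,composition
LN-300 lung,0.30,0.276,7.55,0.03,H:0.0846 C:0.5938 N:0.0196 O:0.1814 Mg:0.1119 Si:0.0078 Cl:0.0010
LN-450 lung,0.45,0.432,7.52,0.03,H:0.0847 C:0.5957 N:0.0197 O:0.1811 Mg:0.1121 Si:0.0058 Cl:0.0010
AP6 adipose,0.92,0.924,6.17,0.02,H:0.0906 C:0.7230 N:0.0225 O:0.1627 Cl:0.0013
BR-12 breast,0.98,0.960,6.87,0.03,H:0.0859 C:0.7011 N:0.0233 O:0.1790 Cl:0.0013 Ca:0.0095
Water insert,1.00,1.000,7.45,0.02,H:0.1119 O:0.8881
CT solid water,1.015,0.990,7.66,0.03,H:0.0802 C:0.6723 N:0.0241 O:0.1991 Cl:0.0014 Ca:0.0231
BRN-SR2 brain,1.05,1.049,6.04,0.03,H:0.1083 C:0.7254 N:0.0169 O:0.1486 Cl:0.0008
LV1 liver,1.10,1.062,7.66,0.03,H:0.0806 C:0.6701 N:0.0247 O:0.2001 Cl:0.0014 Ca:0.0231
IB inner bone,1.14,1.082,10.28,0.03,H:0.0667 C:0.5564 N:0.0196 O:0.2352 P:0.0323 Cl:0.0011 Ca:0.0886
B200 bone mineral,1.15,1.099,10.29,0.03,H:0.0665 C:0.5552 N:0.0198 O:0.2364 P:0.0324 Cl:0.0011 Ca:0.0887
CB2-30% CaCO3,1.34,1.279,10.76,0.02,H:0.0668 C:0.5348 N:0.0212 O:0.2561 Cl:0.0011 Ca:0.1201
CB2-50% CaCO3,1.56,1.471,12.40,0.01,H:0.0477 C:0.4163 N:0.0152 O:0.3200 Cl:0.0008 Ca:0.2002
SB3 cortical bone,1.82,1.693,13.51,0.01,H:0.0341 C:0.3141 N:0.0184 O:0.3650 Cl:0.0004 Ca:0.2681
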