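probe_id	fold_change	p_value
mgU12-22-U4-8_s_st	0.66	0.037
mgU2-25-61_s_st	0.84	0.041
SNORD119_st	0.77	0.03
U104_st	0.77	0.027
U105_st	0.83	0.046
U105B_st	0.39	0.023
U17b_st	0.53	0.025
U17b_x_st	0.58	0.02
U27_st	0.57	0.004
U27_x_st	0.55	0.01
U31_st	0.71	0.031
U31_x_st	0.69	0.035
U42B_x_st	0.79	0.042
U56_st	0.43	0.031
U56_x_st	0.33	0.005
U58A_st	0.85	0.02
U59A_st	0.76	0.014
U61_st	0.66	0.01
U79_st	0.81	0.028
U80_st	0.70	0.018
U83_st	0.65	0.02
U83A_x_st	0.80	0.03
U84_x_st	0.75	0.029
v11_hsa-miR-768-3p_st	0.74	0.028
v11_hsa-miR-768-5p_st	0.86	0.025
ACA16_st	0.76	0.014
ACA16_x_st	0.69	0.002
ACA24_x_st	0.68	0.008
ACA44_s_st	0.50	0.048
ACA48_x_st	0.68	0.005
ACA54_st	0.45	0.003
ACA7_s_st	0.40	0.002
ACA7B_s_st	0.52	0.01
E3_x_st	0.73	0.016
ENSG00000201009_s_st	0.58	0.033
ENSG00000206903_s_st	0.54	0.031
ENSG00000206913_s_st	0.40	0.002
ENSG00000212615_x_st	0.77	0.014
ENSG00000239031_st	1.15	0.039
ENSG00000252049_st	1.10	0.046
HBII-210_st	0.42	0.028
HBII-436_st	0.81	0.018
HBII-55_st	0.62	0.04
HBII-85-17_x_st	0.85	0.031
HBII-85-29_st	0.65	0.004
HBII-85-3_x_st	0.81	0.003
HBII-85-9_x_st	0.87	0.043
HBII-99_st	0.51	0.011
hp_hsa-let-7d_st	0.90	0.044
hp_hsa-mir-423_s_st	0.52	0.023
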