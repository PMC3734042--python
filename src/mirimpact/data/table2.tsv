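mirna_id	fold_change	p_value	ks_p_targetscan	ks_p_miranda
hsa-miR-494	0.14	3.1e-05	1.2e-24	6.0e-81
hsa-miR-15b	0.14	2.5e-03	4.1e-34	5.5e-15
hsa-miR-30c	0.15	7.7e-04	2.8e-13	5.0e-58
hsa-miR-23a	0.16	7.8e-03	2.2e-23	9.8e-63
hsa-miR-197	0.19	5.2e-06	1.6e-12	1.2e-06
hsa-miR-1260b	0.21	9.4e-07	NA	2.3e-16
hsa-miR-125a-5p	0.22	8.2e-03	1.2e-43	5.3e-13
hsa-miR-361-5p	0.24	1.4e-02	1.8e-15	3.9e-32
hsa-miR-320d	0.26	2.8e-03	2.0e-09	7.4e-36
hsa-miR-423-3p	0.26	1.6e-02	5.0e-13	1.8e-03
hsa-miR-1280	0.29	4.7e-03	8.2e-56	8.6e-04
hsa-miR-663	0.32	3.5e-03	5.9e-70	1.8e-28
hsa-miR-423-5p	0.33	2.6e-02	6.1e-96	5.7e-36
hsa-miR-99b	0.36	2.4e-02	3.4e-04	7.6e-03
hsa-miR-339-5p	0.37	4.9e-02	1.5e-35	2.5e-07
hsa-let-7a	0.37	2.9e-02	1.9e-04	3.2e-09
hsa-miR-1979	0.38	1.2e-02	NA	8.1e-09
hsa-miR-3178	0.39	1.0e-02	NA	NS
hsa-miR-625	0.41	3.2e-02	3.6e-62	2.3e-09
hsa-miR-150	0.65	3.7e-02	2.1e-68	2.1e-11
hsa-miR-3153	1.14	4.5e-02	NA	2.4e-09
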