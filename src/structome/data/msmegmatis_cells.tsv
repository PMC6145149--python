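# Published structome profiles of seven M. smegmatis cells, measured on 220
# serial ultrathin sections spanning each cell pole to pole (TEM, rapid
# freeze-substitution).  Values are as printed in the source tables
# (2 decimal places; ribosome densities to the nearest 10).  Lengths were
# measured independently of section count x thickness and are carried
# verbatim ("supplied" length mode).
# units: lengths/diameters um, surfaces um^2, volumes fl, densities per 0.1 fl
cell_id	n_sections	length_um	diam_om_um	diam_pm_um	aspect_ratio	surf_om_um2	surf_pm_um2	vol_whole_fl	vol_om_fl	vol_periplasm_fl	vol_pm_fl	vol_cytoplasm_fl	ribosomes_total	ribosome_density	ribosomes_per_section
1	38	3.90	0.59	0.54	6.63	7.08	6.18	1.06	0.01	0.19	0.03	0.82	9290	1140	245
2	44	3.41	0.60	0.57	5.72	6.24	5.31	0.95	0.01	0.10	0.03	0.81	8580	1060	150
3	21	2.76	0.56	0.53	4.91	4.25	3.89	0.69	0.01	0.08	0.02	0.58	8210	1420	390
4	19	2.16	0.51	0.49	4.26	3.00	2.77	0.44	0.01	0.03	0.01	0.38	5430	1420	290
5	35	3.10	0.66	0.63	4.69	5.89	5.71	1.07	0.01	0.07	0.03	0.96	10630	1110	300
6	28	2.07	0.62	0.59	3.35	3.57	3.37	0.62	0.01	0.04	0.02	0.55	5620	1020	200
7	35	7.41	0.52	0.50	14.35	9.28	8.48	1.55	0.02	0.19	0.04	1.30	12930	990	370
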