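# Published species-level structome summaries (n, mean, sample SD) from
# serial-ultrathin-section studies of six microorganisms, as quoted for
# cross-species comparison.  Metric names follow CellProfile fields; units:
# diameters um, surfaces um^2, volumes fl, densities per 0.1 fl cytoplasm.
# The M. smegmatis rows restate the summaries of the seven-cell table.
group_label	metric	n	mean	sd
M_smegmatis	ribosomes_total	7	8670	2660
M_smegmatis	vol_cytoplasm	7	0.77	0.31
M_smegmatis	ribosome_density	7	1170	180
M_tuberculosis	diam_om	5	0.34	0.03
M_tuberculosis	diam_pm	5	0.30	0.02
M_tuberculosis	aspect_ratio	5	8.24	3.61
M_tuberculosis	surf_om	5	3.03	1.33
M_tuberculosis	surf_pm	5	2.67	1.19
M_tuberculosis	vol_whole	5	0.29	0.11
M_tuberculosis	vol_cytoplasm	5	0.21	0.09
M_tuberculosis	ribosomes_total	5	1670	570
M_tuberculosis	ribosome_density	5	720	170
E_coli	diam_om	9	0.89	0.06
E_coli	aspect_ratio	9	2.84	0.46
E_coli	vol_cytoplasm	9	0.90	0.16
E_coli	ribosomes_total	9	26120	4000
E_coli	ribosome_density	9	2840	120
Myojin_spiral	ribosomes_total	6	320	120
Myojin_spiral	vol_cytoplasm	6	0.18	0.07
Myojin_spiral	ribosome_density	6	220	120
Myojin_amorphous	ribosomes_total	10	1150	370
Myojin_amorphous	vol_cytoplasm	10	0.37	0.09
Myojin_amorphous	ribosome_density	10	310	40
E_dermatitidis	ribosomes_total	5	195000	91100
E_dermatitidis	vol_cytoplasm	5	17.1	6.3
E_dermatitidis	ribosome_density	5	1100	150
S_cerevisiae	ribosomes_total	6	195000	54800
S_cerevisiae	vol_cytoplasm	6	10.0	2.6
S_cerevisiae	ribosome_density	6	1950	100
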