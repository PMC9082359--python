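case_id	germline_hr_gene	somatic_hr_inactivation	hrdetect	low_cellularity	germline_mmr_gene	mlh1	msh2	msh6	pms2	msisensor
348.001	BRCA1	false				retained	retained	retained	retained
1048.001	BRCA1	true	0.999							1.76
PCSI_0476	BRCA1	true	0.999							2.05
70.001	BRCA2	true	0.999			retained	retained	retained	retained	2.17
99.001	BRCA2	false				retained	retained	retained	retained
392.001	BRCA2	true	0.999			retained	retained	retained	retained	1.62
543.001	BRCA2	false				retained	retained	retained	retained
908.001	BRCA2	true	0.999			retained	retained	retained	retained	0.17
1024.001	BRCA2	true	0.999							2.2
1183.001	BRCA2	false				retained	retained	retained	retained
1195.001	BRCA2	false				retained	retained	retained	retained
1227.001	BRCA2	false				retained	retained	retained	retained
1235.001	BRCA2	false
1337.001	BRCA2	false				retained	retained	retained	retained
PCSI_0017	BRCA2	true	0.999							2.44
PCSI_0048	BRCA2	true	0.999			retained	retained	retained	retained	0.96
PCSI_0075		true	0.999			retained	retained	retained	retained	1.46
PCSI_0142	BRCA2	true	0.999			retained	retained	retained	retained	1.74
PCSI_0176	BRCA2	true	0.999							1.14
PCSI_0218	BRCA2	true	0.999			retained	retained	retained	retained	0.73
PCSI_0472		true	0.999							2.32
PCSI_0477	BRCA2	true	0.999							1.69
PCSI_0492	BRCA2	true	0.999							2.80
303.001	PALB2	true	0.742	true		retained	retained	retained	retained	1.36
1099.001	PALB2	false				retained	retained	retained	retained
750.001		false			MSH2	retained	lost	lost	retained
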