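category	gene_id	function	log2fc	q
Wax Biosynthesis	Solyc05g013220	Ketoacyl-CoA synthase KCS	-1.97	5.0E-62
Wax Biosynthesis	Solyc06g074390	Fatty acyl-CoA reductase FAR1	1.24	3.5E-17
Wax Biosynthesis	Solyc03g117800	ECERIFERUM 3 CER3	-1.28	6.4E-58
Wax Biosynthesis	Solyc10g080840	Cytochrome P450 MAH1	-1.86	8.6E-209
Cutin Biosynthesis	Solyc08g081220	Cytochrome P450 CYP86A69 CD3	-2.20	1.3E-254
Cutin Biosynthesis	Solyc04g082380	Cytochrome P450 CYP86A8-like	-1.10	4.4E-08
Cutin Biosynthesis	Solyc09g014350	Glycerol-3-phosphate acyltransferase GPAT6	-1.20	8.9E-69
Lipid Transport	Solyc10g075100	Non-specific lipid-transfer protein LTP2_1e	2.98	0.0E+00
Lipid Transport	Solyc09g018010	Non-specific lipid-transfer protein LTP2_2	1.37	6.9E-16
Lipid Transport	Solyc10g075110	Non-specific lipid-transfer protein LTP2_1f	2.50	8.4E-31
Lipid Transport	Solyc08g067540	Non-specific lipid-transfer protein	1.57	3.4E-07
Lipid Transport	Solyc05g015490	Plant lipid transfer protein LTPG1	-3.37	7.0E-88
Polymerization	Solyc02g071610	GDSL esterase/lipase	1.58	7.3E-93
Polymerization	Solyc02g071700	GDSL esterase/lipase	2.41	2.1E-50
Polymerization	Solyc07g049440	GDSL esterase/lipase	-1.88	0.0E+00
Polymerization	Solyc03g121180	GDSL esterase/lipase	1.08	6.8E-74
Polymerization	Solyc10g076740	GDSL esterase/lipase CPRD49	-1.10	8.9E-29
Polymerization	Solyc11g006250	GDSL esterase/lipase CUS1	1.22	1.4E-69
Polymerization	Solyc06g083650	GDSL esterase/lipase CUS4	-1.12	1.1E-33
Polymerization	Solyc08g008610	Alpha/beta-Hydrolases superfamily protein BDG1	3.53	7.1E-151
Regulation	Solyc02g088190	SlMIXTA-like	-1.08	1.0E-59
Phenylpropanoid Pathway	Solyc05g056170	Phenylalanine ammonia-lyase	-1.84	1.6E-122
Phenylpropanoid Pathway	Solyc09g007890	Phenylalanine ammonia-lyase	1.17	4.8E-87
Phenylpropanoid Pathway	Solyc10g086180	Phenylalanine ammonia-lyase	1.57	3.3E-42
Phenylpropanoid Pathway	Solyc09g007910	Phenylalanine ammonia-lyase	2.47	2.8E-202
Phenylpropanoid Pathway	Solyc00g500353	Phenylalanine ammonia-lyase	4.59	0.0E+00
Phenylpropanoid Pathway	Solyc09g007920	Phenylalanine ammonia-lyase	1.08	7.8E-84
Phenylpropanoid Pathway	Solyc02g093230	Caffeoyl-CoA O-methyltransferase	1.78	9.9E-34
Phenylpropanoid Pathway	Solyc02g093250	Caffeoyl-CoA O-methyltransferase	1.79	2.9E-50
Phenylpropanoid Pathway	Solyc09g091510	Chalcone synthase 1 CHS1	1.91	6.6E-121
Phenylpropanoid Pathway	Solyc01g111070	Chalcone synthase-like	1.32	3.6E-30
Cell Wall	Solyc12g015770	Cellulose synthase	-2.00	3.7E-83
Cell Wall	Solyc07g043390	Cellulose synthase	1.67	5.3E-41
Cell Wall	Solyc03g097050	Cellulose synthase	3.96	0.0E+00
Cell Wall	Solyc02g089640	Cellulose-synthase-like C4	1.71	1.8E-189
Cell Wall	Solyc01g065530	COBRA-like protein	1.92	2.2E-221
Cell Wall	Solyc08g081620	Endo-1,4-beta-glucanase precursor	-1.05	1.9E-07
Cell Wall	Solyc08g082250	Endo-beta-1,4-D-glucanase Cel8	1.01	7.5E-88
Cell Wall	Solyc07g049300	Endoglucanase	1.18	1.5E-61
Cell Wall	Solyc07g064870	Endoglucanase	1.59	5.1E-71
Cell Wall	Solyc03g071570	Pectate lyase	1.29	3.0E-60
Cell Wall	Solyc09g091430	Pectate lyase	1.90	9.2E-102
Cell Wall	Solyc09g061890	Pectate lyase	2.26	5.4E-231
Cell Wall	Solyc04g082140	Pectinesterase	1.31	4.6E-116
Cell Wall	Solyc06g009190	Pectinesterase	1.20	7.4E-36
Cell Wall	Solyc03g123620	Pectinesterase	2.71	0.0E+00
Cell Wall	Solyc03g083730	Plant invertase/pectin methylesterase inhibitor	1.65	2.8E-12
Cell Wall	Solyc12g010540	UDP-glucuronate 4-epimerase 4	1.70	3.9E-135
Cell Wall	Solyc05g051260	1,4-beta-xylanase	2.40	8.5E-07
Cell Wall	Solyc03g093080	Xyloglucan endotransglucosylase/hydrolase	3.50	0.0E+00
Cell Wall	Solyc07g055990	Xyloglucan endotransglucosylase/hydrolase	4.05	4.4E-208
Cell Wall	Solyc02g080160	Xyloglucan endotransglucosylase/hydrolase	1.62	3.6E-101
Cell Wall	Solyc07g056000	Xyloglucan endotransglucosylase/hydrolase	3.09	0.0E+00
Cell Wall	Solyc03g093110	Xyloglucan endotransglucosylase/hydrolase	3.96	0.0E+00
Cell Wall	Solyc07g009380	Xyloglucan endotransglucosylase-hydrolase 2	-1.14	3.0E-86
Cell Wall	Solyc03g093130	Xyloglucan endotransglucosylase-hydrolase 3	4.19	0.0E+00
Cell Wall	Solyc12g011030	Xyloglucan endotransglucosylase-hydrolase 9	3.02	5.7E-234
Cell Wall	Solyc12g017240	Xyloglucan endo-transglycosylase B1	2.73	0.0E+00
Cell Wall	Solyc07g044960	Xyloglucan galactosyltransferase KATAMARI1	3.89	6.7E-72
Cell Wall	Solyc03g093120	Xyloglucan:xyloglucosyl transferase TCH4	4.87	0.0E+00
Cell Wall	Solyc06g074670	UDP-apiose/UDP-xylose synthase	2.57	0.0E+00
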