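category	gene_id	function	log2fc	q
Gibberellin	Solyc12g006460	GA ent-kaurenoate oxidase	4.26	2.5E-249
Gibberellin	Solyc07g056670	Gibberellin 2-oxidase	-3.52	4.2E-46
Gibberellin	Solyc09g074270	Gibberellin receptor	2.34	1.1E-87
Gibberellin	Solyc04g017720	Gibberellin regulated protein GASA6	-2.04	2.3E-17
Gibberellin	Solyc04g078195	Gibberellin-regulated protein	1.12	5.0E-84
Ethylene synthesis and signalling	Solyc07g049550	1-aminocyclopropane-1-carboxylate oxidase 2 ACO2	-3.35	3.8E-26
Ethylene synthesis and signalling	Solyc07g026650	1-aminocyclopropane-1-carboxylate oxidase 5 ACO5	-1.47	2.3E-13
Ethylene synthesis and signalling	Solyc02g091990	Aminocyclopropane-1-carboxylate synthase 3 ACS3	3.48	1.4E-74
Ethylene synthesis and signalling	Solyc09g089610	Ethylene receptor-like protein ETR6	-1.81	5.3E-38
Ethylene response	Solyc10g006130	EAR motif SlERF36	1.30	3.1E-135
Ethylene response	Solyc05g052030	Ethylene response factor 4	-3.90	8.6E-42
Ethylene response	Solyc03g093610	Ethylene response factor A.2	2.42	3.0E-144
Ethylene response	Solyc04g014530	Ethylene response factor C.2	-1.08	7.0E-14
Ethylene response	Solyc02g077370	Ethylene response factor C.5	1.74	2.1E-29
Ethylene response	Solyc03g093560	Ethylene response factor C.6	2.32	2.5E-35
Ethylene response	Solyc01g108240	Ethylene response factor D.3	3.96	0.0E+00
Ethylene response	Solyc10g050970	Ethylene response factor D.4	4.26	0.0E+00
Ethylene response	Solyc07g053740	Ethylene response factor F.4	1.29	2.1E-20
Ethylene response	Solyc05g051200	Ethylene-responsive factor 1	-2.02	6.8E-31
Ethylene response	Solyc04g011440	Ethylene-responsive heat shock protein cognate 70	2.44	0.0E+00
Ethylene response	Solyc02g070040	Ethylene-responsive nuclear protein ERT2	4.10	3.8E-135
Ethylene response	Solyc08g080630	Ethylene-responsive proteinase inhibitor 1	-7.90	4.6E-25
Ethylene response	Solyc12g056980	Ethylene-responsive transcription factor	-1.18	4.6E-15
Ethylene response	Solyc11g012980	Ethylene-responsive transcription factor	1.52	1.2E-62
Ethylene response	Solyc06g035700	Ethylene-responsive transcription factor	3.60	5.2E-59
Ethylene response	Solyc11g042560	Ethylene-responsive transcription factor	5.27	3.6E-56
Ethylene response	Solyc08g082210	Ethylene-responsive transcription factor	-1.43	2.3E-43
Ethylene response	Solyc12g009240	Ethylene-responsive transcription factor	1.26	3.2E-107
Ethylene response	Solyc01g090560	Ethylene-responsive transcription factor	1.60	3.3E-30
Ethylene response	Solyc01g090340	Ethylene-responsive transcription factor 2	3.88	3.5E-77
Ethylene response	Solyc02g077840	Ethylene-responsive transcription factor 4	1.17	1.1E-18
Ethylene response	Solyc08g078190	Ethylene-responsive transcription factor 5	1.15	1.7E-32
Ethylene response	Solyc03g093550	Ethylene-responsive transcription factor 5	1.62	4.6E-72
Ethylene response	Solyc03g093540	Ethylene-responsive transcription factor 5	2.28	6.1E-12
Ethylene response	Solyc04g078640	Ethylene-responsive transcription factor RAP2-1	-1.85	8.0E-11
Auxin synthesis, transport and response	Solyc06g062920	Auxin-regulated dual specificity cytosolic kinase	2.57	4.1E-236
Auxin synthesis, transport and response	Solyc03g120380	Auxin-regulated IAA19	1.51	2.0E-37
Auxin synthesis, transport and response	Solyc06g008580	Auxin-regulated IAA22	1.69	2.4E-22
Auxin synthesis, transport and response	Solyc08g021820	Auxin-regulated IAA29	-2.31	5.2E-31
Auxin synthesis, transport and response	Solyc12g096570	Auxin-regulated organ size gene	-4.27	1.6E-31
Auxin synthesis, transport and response	Solyc06g075690	Auxin-regulated protein AF416289	4.87	5.5E-203
Auxin synthesis, transport and response	Solyc04g053010	Auxin-responsive protein SAUR65	1.56	3.4E-74
Auxin synthesis, transport and response	Solyc01g099840	Dormancy/auxin associated protein	-1.15	1.3E-44
Auxin synthesis, transport and response	Solyc10g079640	IAA-amino acid hydrolase ILR1-like 6	1.74	2.1E-76
Auxin synthesis, transport and response	Solyc06g059730	PIN6	6.11	3.3E-51
Auxin synthesis, transport and response	Solyc01g110920	Small auxin up-regulated RNA26	-1.06	2.0E-18
Auxin synthesis, transport and response	Solyc04g081250	Small auxin up-regulated RNA51	-1.39	2.4E-17
Auxin synthesis, transport and response	Solyc04g081270	Small auxin up-regulated RNA52	-1.93	8.6E-24
Abscisic Acid	Solyc02g084850	Abscisic acid environmental stress-inducible protein TAS14	1.13	3.8E-08
Abscisic Acid	Solyc03g095780	Abscisic acid receptor PYL4-like	1.99	3.7E-48
Abscisic Acid	Solyc08g005610	Cytochrome P450 CYP707A ABA	3.18	4.3E-26
Brassinosteroid	Solyc02g071990	Brassinosteroid signaling positive regulator-related protein BES1/BZR1	1.20	1.9E-55
Brassinosteroid	Solyc07g062260	Brassinosteroid signaling positive regulator-related protein BES1/BZR1	1.55	6.4E-34
Cytokinin	Solyc11g069570	Cytokinin riboside 5'-monophosphate phosphoribohydrolase	1.26	8.0E-12
Jasmonate	Solyc09g061840	3-ketoacyl-CoA thiolase peroxisomal-like	1.02	2.8E-26
Jasmonate	Solyc07g006890	Cytochrome P450 CYP94B jasmonate	3.01	0.0E+00
Jasmonate	Solyc12g009220	Jasmonate ZIM-domain protein 1	6.33	2.1E-139
Jasmonate	Solyc07g042170	Jasmonate ZIM-domain protein 3	1.82	3.9E-187
Jasmonate	Solyc08g076930	Jasmonic acid 3	1.11	3.2E-76
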