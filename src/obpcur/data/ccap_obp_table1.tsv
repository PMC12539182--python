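name	accession	aa_length	signal_peptide	classification	hit_accession	hit_description	evalue	identity_pct	coverage_pct
CcapOBP19a	XP_004525133	147	1-24	Classical	NP_728338.2	OBP19a	6.04E-60	55.17	98
CcapOBP19a-like	PQ528246	147	1-27	Classical	NP_728338.2	OBP19a	2.46E-54	60.00	83
CcapOBP19b	PQ528247	151	1-20	Classical	NP_608391.2	OBP19b	8.82E-34	37.58	98
CcapOBP19b-like	PQ528248	124	1-25	Classical	NP_523421.2	OBP19d isoform A	1.78E-12	29.63	84
CcapOBP19c	PQ528249	175	–	Classical	NP_608392.1	OBP19c isoform A	4.09E-21	25.20	74
CcapOBP19c-like	PQ528250	253	1-19	Plus-C	NP_611443.1	OBP56b	0.019634	24.51	65
CcapOBP19d	XP_004525035	142	1-21	Classical	NP_523421.2	OBP19d isoform A	7.45E-29	42.73	77
CcapOBP19d-like	PQ528251	143	1-21	Classical	NP_523421.2	OBP19d isoform A	6.52E-20	31.30	80
CcapOBP28a	PQ528252	147	1-21	Classical	NP_523505.1	OBP28a	1.59E-46	48.55	94
CcapOBP44a-isoform1	PQ528253	142	1-18	Classical	NP_610358.1	OBP44a isoform A	1.85E-62	61.54	100
CcapOBP44a-isoform2	PQ528254	142	1-18	Classical	NP_610358.1	OBP44a isoform A	1.03E-60	60.14	100
CcapOBP50e-like	PQ528255	179	1-22	Plus-C	NP_610959.2	OBP50e	9.86E-12	21.33	76
CcapOBP47a	CAD7013140	195	–	Classical	NP_610632.1	OBP47a isoform A	2.20E-31	41.59	57
CcapOBP47b	XP_012162233	199	1-29	Plus-C	NP_610669.1	OBP47b	2.43E-68	50.00	97
CcapOBP49a	PQ528256	221	1-21	Plus-C	NP_610812.1	OBP49a	4.55E-25	31.93	96
CcapOBP56b	XP_004517903	138	1-25	Classical	NP_611443.1	OBP56b	2.74E-23	36.64	90
CcapOBP56b-like1	XP_020718148	165	1-25	Classical	NP_611442.1	OBP56a	9.89E-14	28.07	64
CcapOBP56b-like2	XP_020718149	138	1-25	Classical	NP_611442.1	OBP56a	8.81E-14	28.07	64
CcapOBP56c	XP_012155938	327	–	Classical	NP_725925.3	OBP56c isoform C	1.50E-32	31.90	70
CcapOBP56d	PQ528257	137	1-19	Classical	NP_611444.2	OBP56d isoform A	2.78E-34	42.22	99
CcapOBP56e	XP_004517904	135	1-20	Classical	NP_611444.2	OBP56d isoform A	1.61E-23	36.22	93
CcapOBP56g	PQ528258	124	1-20	Classical	NP_611448.2	OBP56h isoform A	7.76E-23	34.65	95
CcapOBP56h1	PQ528259	136	1-20	Classical	NP_611448.2	OBP56h isoform A	6.76E-30	38.40	92
CcapOBP56h2	XP_004517905	138	1-20	Classical	NP_611448.2	OBP56h isoform A	9.75E-28	37.88	96
CcapOBP57c	PQ528260	186	1-33	Classical	NP_611481.1	OBP57c	4.81E-17	27.56	66
CcapOBP58c	XP_004537654	201	1-21	Plus-C	NP_611710.1	OBP58c	1.07E-95	62.56	97
CcapOBP59a	PQ528261	342	1-28	Plus-C	NP_788429.1	OBP59a	2.97E-37	60.22	39
CcapOBP69a	NP_001295335	147	1-24	Classical	NP_524039.2	OBP69a	1.48E-31	36.84	90
CcapOBP73a	PQ528262	102	1-21	Plus-C	NP_001334711.1	OBP73a isoform C	4.50E-90	51.98	95
CcapOBP83a	PQ528263	157	1-34	Classical	NP_001287190.1	OBP83a isoform C	3.66E-82	69.43	100
CcapOBP83a-like	PQ528264	148	1-24	Classical	NP_524241.1	OBP83a isoform A	3.58E-57	55.17	97
CcapOBP83cd	PQ528265	241	1-21	Atypical	NP_649612.1	OBP83cd	3.46E-78	46.08	88
CcapOBP83ef	PQ528266	277	1-25	Atypical	NP_731042.1	OBP83ef	1.31E-75	49.06	74
CcapOBP83g	PQ528267	142	1-18	Classical	NP_731043.1	OBP83g	1.21E-66	62.14	95
CcapOBP84a	PQ528268	178	1-24	Plus-C	NP_476990.1	OBP84a isoform A	4.64E-41	50.00	62
CcapOBP84a-like	XP_004529369	177	1-35	Plus-C	NP_476990.1	OBP84a isoform A	3.52E-38	38.73	93
CcapOBP8a	PQ528269	162	1-29	Minus-C	NP_727322.1	OBP8a	1.11E-21	32.77	69
CcapOBP99b	PQ528270	149	1-18	Classical	NP_651707.1	OBP99a isoform A	2.95E-48	45.78	95
CcapOBP99c	PQ528271	101	1-16	Minus-C	NP_651711.1	OBP99c isoform A	1.32E-61	56.84	93
CcapOBP99c-like1a	XP_004536902	142	1-16	Minus-C	NP_651711.1	OBP99c isoform A	4.00E-28	39.69	92
CcapOBP99c-like1b	XP_023158406	142	1-16	Minus-C	NP_651711.1	OBP99c isoform A	7.00E-57	38.93	92
CcapOBP99c-like2	PQ528273	144	1-16	Minus-C	NP_651711.1	OBP99c isoform A	1.94E-31	39.39	92
CcapOBP99c-like3	NP_001266316	144	1-16	Minus-C	NP_651711.1	OBP99c isoform A	9.22E-29	40.88	95
CcapOBP99c-like4a	XP_004536905	143	1-16	Minus-C	NP_651711.1	OBP99c isoform A	1.00E-17	31.25	89
CcapOBP99c-like4b	NP_001295338	143	1-16	Minus-C	NP_651711.1	OBP99c isoform A	4.78E-24	36.84	93
CcapOBP99c-like5	PQ528272	144	1-16	Minus-C	NP_651711.1	OBP99c isoform A	2.24E-28	40.30	93
CcapOBP99d	PQ528274	150	1-16	Minus-C	NP_651712.1	OBP99d	3.04E-26	42.71	63
CcapOBPlush	XP_004522281	152	1-16	Classical	NP_728338.2	OBP19a	1.17E-20	31.29	89
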