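author	year	gene	variant	comparison	odds_ratio	ci_lower	ci_upper	p_value	study_type	ethnicity	subtype	n_cases	n_controls	n_studies	fprp_1.2_0.001	fprp_1.2_1e-06	fprp_1.5_0.001	fprp_1.5_1e-06	bfdp_0.001	bfdp_1e-06
Chang X	2018	NMUR2	rs1946225	G vs. T	2.29	1.73	3.05	9.55E-09	gwas	Overall 3 (European 1, African 2)	overall	1212	13494	3	0.717	1.000	0.006	0.851	0.027	0.965
Chang X	2018	NMUR2	rs72793414	A vs. G	2.44	1.85	3.23	3.81E-10	gwas	Overall 3 (European 1, African 2)	overall	1212	13494	3	0.545	0.999	0.001	0.541	0.003	0.743
Gormley P	2016	LRP1	rs11172113	C vs. T	0.90	0.89	0.91	5.6E-49	gwas	Overall (Caucasian 22)	overall	59674	316078	22	-	-	-	-	6.004E-72	6.011E-69
Gormley P	2016	PRDM16	rs10218452	G vs. A	1.11	1.10	1.13	5.3E-38	gwas	Overall (Caucasian 22)	overall	59674	316078	22	-	-	-	-	8.348E-25	8.356E-22
Gormley P	2016	FHL5	rs67338227	T vs. A	1.09	1.08	1.11	2.0E-27	gwas	Overall (Caucasian 22)	overall	59674	316078	22	-	-	-	-	4.430E-15	4.435E-12
Gormley P	2016	TSPAN2	rs2078371	C vs. T	1.11	1.09	1.13	4.1E-24	gwas	Overall (Caucasian 22)	overall	59674	316078	22	-	-	-	-	8.348E-25	8.356E-22
Gormley P	2016	TRPM8	rs10166942	C vs. T	0.94	0.89	0.99	1.0E-23	gwas	Overall (Caucasian 22)	overall	59674	316078	22	0.951	1.000	0.951	1.000	0.998	1.000
Gormley P	2016	PHACTR1	rs9349379	G vs. A	0.93	0.92	0.95	5.8E-22	gwas	Overall (Caucasian 22)	overall	59674	316078	22	2.308E-08	2.310E-05	2.308E-08	2.310E-05	4.007E-06	3.995E-03
Gormley P	2016	MEF2D	rs1925950	A vs. G	1.07	1.06	1.09	9.1E-22	gwas	Overall (Caucasian 22)	overall	59674	316078	22	8.014E-10	8.022E-07	8.014E-10	8.022E-07	1.694E-07	1.695E-04
Gormley P	2016	SLC24A3	rs4814864	C vs. G	1.07	1.06	1.09	2.2E-19	gwas	Overall (Caucasian 22)	overall	59674	316078	22	8.014E-10	8.022E-07	8.014E-10	8.022E-07	1.694E-07	1.695E-04
Gormley P	2016	FGF6	rs1024905	A vs. G	1.06	1.04	1.08	2.1E-17	gwas	Overall (Caucasian 22)	overall	59674	316078	22	9.959E-07	9.959E-04	9.959E-07	9.959E-04	1.767E-04	0.150
Gormley P	2016	C7orf10	rs186166891	T vs. A	1.09	1.07	1.12	9.7E-16	gwas	Overall (Caucasian 22)	overall	59674	316078	22	4.993E-07	4.935E-04	4.993E-07	4.935E-04	6.430E-05	6.048E-02
Gormley P	2016	PLCE1	rs10786156	G vs. C	0.95	0.94	0.96	2.0E-14	gwas	Overall (Caucasian 22)	overall	59674	316078	22	-	-	-	-	3.842E-16	3.846E-13
Gormley P	2016	KCNK5	rs10456100	T vs. C	1.06	1.04	1.07	6.9E-13	gwas	Overall (Caucasian 22)	overall	59674	316078	22	-	-	-	-	3.372E-28	3.376E-25
Gormley P	2016	ASTN2	rs6478241	T vs. A	1.05	1.04	1.07	1.2E-12	gwas	Overall (Caucasian 22)	overall	59674	316078	22	4.011E-04	0.287	4.011E-04	0.287	0.055	0.983
Gormley P	2016	MRVI1	rs4910165	G vs. C	0.94	0.91	0.98	2.9E-11	gwas	Overall (Caucasian 22)	overall	59674	316078	22	0.783	1.000	0.783	1.000	0.993	1.000
Gormley P	2016	HPSE2	rs12260159	A vs. G	0.92	0.89	0.94	3.2E-10	gwas	Overall (Caucasian 22)	overall	59674	316078	22	2.979E-11	2.982E-08	2.979E-11	2.982E-08	5.906E-09	5.912E-06
Gormley P	2016	CFDP1	rs77505915	A vs. T	1.05	1.03	1.06	3.3E-10	gwas	Overall (Caucasian 22)	overall	59674	316078	22	-	-	-	-	3.476E-18	3.479E-15
Gormley P	2016	RNF213	rs17857135	C vs. T	1.06	1.04	1.08	5.2E-10	gwas	Overall (Caucasian 22)	overall	59674	316078	22	9.959E-07	9.959E-04	9.959E-07	9.959E-04	1.767E-04	0.150
Gormley P	2016	NRP1	rs2506142	G vs. A	1.06	1.04	1.07	1.5E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	-	-	-	-	3.372E-28	3.376E-25
Gormley P	2016	GPR149	rs13078967	C vs. A	0.87	0.83	0.91	1.8E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	1.300E-06	1.299E-03	1.260E-06	1.260E-03	1.117E-04	0.101
Gormley P	2016	JAG1	rs111404218	G vs. C	1.05	1.03	1.07	2.0E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	4.011E-04	0.287	4.011E-04	0.287	0.055	0.983
Gormley P	2016	SPINK2	rs7684253	T vs. C	0.96	0.94	0.97	2.5E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	1.153E-11	1.154E-08	1.153E-11	1.154E-08	4.525E-09	4.530E-06
Gormley P	2016	ZCCHC14	rs4081947	G vs. A	1.03	1.00	1.06	2.5E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	0.978	1.000	0.978	1.000	1.000	1.000
Gormley P	2016	HEY2	rs1268083	C vs. T	0.96	0.95	0.97	5.3E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	1.153E-11	1.154E-08	1.153E-11	1.154E-08	4.525E-09	4.530E-06
Gormley P	2016	WSCD1	rs75213074	T vs. C	0.89	0.86	0.93	7.1E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	2.044E-04	0.170	2.040E-04	0.170	0.015	0.937
Gormley P	2016	GJA1	rs28455731	T vs. G	1.06	1.04	1.08	7.3E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	9.959E-07	9.959E-04	9.959E-07	9.959E-04	1.767E-04	0.150
Gormley P	2016	TGFBR2	rs6791480	T vs. C	1.04	1.03	1.06	7.8E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	0.052	0.982	0.052	0.982	0.863	1.000
Gormley P	2016	ITPK1	rs11624776	C vs. A	0.96	0.94	0.97	7.9E-09	gwas	Overall (Caucasian 22)	overall	59674	316078	22	1.153E-11	1.154E-08	1.153E-11	1.154E-08	4.525E-09	4.530E-06
Gormley P	2016	ADAMTSL4	rs6693567	T vs. C	1.05	1.03	1.06	1.2E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	-	-	-	-	3.476E-18	3.479E-15
Gormley P	2016	CCM2L	rs144017103	T vs. C	0.85	0.76	0.96	1.2E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	0.934	1.000	0.899	1.000	0.993	1.000
Gormley P	2016	YAP1	rs10895275	A vs. T	1.04	1.03	1.06	1.6E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	0.052	0.982	0.052	0.982	0.863	1.000
Gormley P	2016	MED14	rs12845494	G vs. C	0.96	0.95	0.97	1.7E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	1.153E-11	1.154E-08	1.153E-11	1.154E-08	4.525E-09	4.530E-06
Gormley P	2016	DOCK4	rs10155855	T vs. A	1.08	1.05	1.12	2.1E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	0.032	0.971	0.032	0.971	0.688	1.000
Gormley P	2016	LRRIQ3	rs1572668	G vs. A	1.04	1.02	1.05	2.1E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	8.873E-13	8.882E-10	8.873E-13	8.882E-10	4.186E-10	4.190E-07
Gormley P	2016	CARF	rs138556413	G vs. A	0.88	0.84	0.92	2.3E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	1.748E-05	0.017	1.733E-05	0.017	1.395E-03	0.583
Gormley P	2016	ARMS2	rs2223089	C vs. G	0.93	0.91	0.95	3.0E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	2.308E-08	2.310E-05	2.308E-08	2.310E-05	4.007E-06	3.995E-03
Gormley P	2016	IGSF9B	rs561561	T vs. A	0.94	0.92	0.96	3.4E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	8.384E-06	0.008	8.384E-06	0.008	1.254E-03	0.557
Gormley P	2016	MPPED2	rs11031122	C vs. T	1.04	1.03	1.06	3.5E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	0.052	0.982	0.052	0.982	0.863	1.000
Gormley P	2016	NOTCH4	rs140002913	A vs. G	0.91	0.88	0.94	3.8E-08	gwas	Overall (Caucasian 22)	overall	59674	316078	22	1.204E-05	0.012	1.204E-05	0.012	1.229E-03	0.552
Anttila V	2013	PRDM16	rs2651899	C vs. T	1.09	1.07	1.12	3.28E-14	gwas	Overall (Caucasian 19)	overall	23285	95425	19	4.933E-07	4.935E-04	4.933E-07	4.935E-04	6.430E-05	0.0605
Anttila V	2013	TSPAN2	rs12134493	A vs. C	1.14	1.10	1.18	6.71E-14	gwas	Overall (Caucasian 19)	overall	23285	95425	19	9.555E-11	9.565E-08	9.538E-11	9.548E-08	1.305E-08	1.307E-05
Anttila V	2013	MEF2D	rs2274316	C vs. A	1.07	1.04	1.09	3.14E-08	gwas	Overall (Caucasian 19)	overall	23285	95425	19	8.014E-10	8.022E-07	8.014E-10	8.022E-07	1.694E-07	1.695E-04
Anttila V	2013	TRPM8	rs7577262	A vs. G	0.87	0.84	0.90	3.27E-13	gwas	Overall (Caucasian 19)	overall	23285	95425	19	8.231E-13	8.239E-10	8.180E-13	8.188E-10	1.259E-10	1.260E-07
Anttila V	2013	FHL5	rs13208321	A vs. T	1.18	1.13	1.24	2.15E-12	gwas	Overall (Caucasian 19)	overall	23285	95425	19	8.181E-08	8.189E-05	6.109E-08	6.115E-05	5.781E-06	5.753E-03
Anttila V	2013	c7orf10	rs4379368	T vs. C	1.11	1.08	1.15	1.46E-09	gwas	Overall (Caucasian 19)	overall	23285	95425	19	7.560E-06	7.511E-03	7.560E-06	7.511E-03	7.339E-04	0.424
Anttila V	2010	MTDH	rs1835740	C vs. T	1.18	1.13	1.24	1.60E-11	gwas	Overall (Caucasian 7)	overall	5950	50809	7	1.109E-06	1.109E-03	8.138E-07	8.139E-04	6.811E-05	0.064
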