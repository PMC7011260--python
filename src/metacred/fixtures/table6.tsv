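author	year	gene	variant	comparison	odds_ratio	ci_lower	ci_upper	p_value	study_type	ethnicity	subtype	n_cases	n_controls	n_studies	maf	par_percent	joint_par_percent
Chang X	2018	NMUR2	rs72793414	A vs. G	2.44	1.85	3.23	3.81E-10	gwas	Overall 2	overall	1212	13494	2	0.1082	13.4804396578	44.2094776354
Gormley P	2016	LRP1	rs11172113	C vs. T	0.90	0.89	0.91	5.6E-49	gwas	Caucasian 22	overall	59674	316078	22	0.3894	4.0517761638	
Gormley P	2016	PRDM 16	rs10218452	G vs. A	1.11	1.10	1.13	5.3E-38	gwas	Caucasian 22	overall	59674	316078	22	0.2264	2.4298861162	
Gormley P	2016	FHL5	rs67338227	T vs. A	1.09	1.08	1.11	2.0E-27	gwas	Caucasian 22	overall	59674	316078	22	0.0220	0.1976087347	
Gormley P	2016	TSPAN2	rs2078371	C vs. T	1.11	1.09	1.13	4.1E-24	gwas	Caucasian 22	overall	59674	316078	22	0.1252	1.3584908638	
Gormley P	2016	PHACTR1	rs9349379	G vs. A	0.93	0.92	0.95	5.8E-22	gwas	Caucasian 22	overall	59674	316078	22	0.3774	2.7134848426	
Gormley P	2016	MEF2D	rs1925950	A vs. G	1.07	1.06	1.09	9.1E-22	gwas	Caucasian 22	overall	59674	316078	22	0.4277	2.9068711836	
Gormley P	2016	SLC24A3	rs4814864	C vs. G	1.07	1.06	1.09	2.2E-19	gwas	Caucasian 22	overall	59674	316078	22	0.3021	2.0709065394	
Gormley P	2016	FGF6	rs1024905	A vs. G	1.06	1.04	1.08	2.1E-17	gwas	Caucasian 22	overall	59674	316078	22	0.3165	1.8636100452	
Gormley P	2016	C7orf10	rs186166891	T vs. A	1.09	1.07	1.12	9.7E-16	gwas	Caucasian 22	overall	59674	316078	22	0.1631	1.4466644131	
Gormley P	2016	PLCE1	rs10786156	G vs. C	0.95	0.94	0.96	2.0E-14	gwas	Caucasian 22	overall	59674	316078	22	0.4852	2.4863180765	
Gormley P	2016	KCNK5	rs10456100	T vs. C	1.06	1.04	1.07	6.9E-13	gwas	Caucasian 22	overall	59674	316078	22	0.1813	1.0760942468	
Gormley P	2016	HPSE2	rs12260159	A vs. G	0.92	0.89	0.94	3.2E-10	gwas	Caucasian 22	overall	59674	316078	22	0.1673	1.3565561475	
Gormley P	2016	CFDP1	rs77505915	A vs. T	1.05	1.03	1.06	3.3E-10	gwas	Caucasian 22	overall	59674	316078	22	0.4898	2.3904576911	
Gormley P	2016	RNF213	rs17857135	C vs. T	1.06	1.04	1.08	5.2E-10	gwas	Caucasian 22	overall	59674	316078	22	0.2115	1.2530981840	
Gormley P	2016	NRP1	rs2506142	G vs. A	1.06	1.04	1.07	1.5E-09	gwas	Caucasian 22	overall	59674	316078	22	0.1865	1.1066169563	
Gormley P	2016	GPR149	rs13078967	C vs. A	0.87	0.83	0.91	1.8E-09	gwas	Caucasian 22	overall	59674	316078	22	0.0110	0.1432047828	
Gormley P	2016	SPINK2	rs7684253	T vs. C	0.96	0.94	0.97	2.5E-09	gwas	Caucasian 22	overall	59674	316078	22	0.4499	1.8325790934	
Gormley P	2016	HEY2	rs1268083	C vs. T	0.96	0.95	0.97	5.3E-09	gwas	Caucasian 22	overall	59674	316078	22	0.4419	1.7994063059	
Gormley P	2016	WSCD1	rs75213074	T vs. C	0.89	0.86	0.93	7.1E-09	gwas	Caucasian 22	overall	59674	316078	22	0.0094	0.1035070263	
Gormley P	2016	GJA1	rs28455731	T vs. G	1.06	1.04	1.08	7.3E-09	gwas	Caucasian 22	overall	59674	316078	22	0.1302	0.7751445706	
Gormley P	2016	ITPK1	rs11624776	C vs. A	0.96	0.94	0.97	7.9E-09	gwas	Caucasian 22	overall	59674	316078	22	0.2278	0.9195792057	
Gormley P	2016	ADAMTSL4	rs6693567	T vs. C	1.05	1.03	1.06	1.2E-08	gwas	Caucasian 22	overall	59674	316078	22	0.3037	1.4957864823	
Gormley P	2016	MED14	rs12845494	G vs. C	0.96	0.95	0.97	1.7E-08	gwas	Caucasian 22	overall	59674	316078	22	0.4114	1.6731330779	
Gormley P	2016	LRRIQ3	rs1572668	G vs. A	1.04	1.02	1.05	2.1E-08	gwas	Caucasian 22	overall	59674	316078	22	0.4930	1.9338641980	
Gormley P	2016	CARF	rs138556413	G vs. A	0.88	0.84	0.92	2.3E-08	gwas	Caucasian 22	overall	59674	316078	22	0.0104	0.1249559450	
Gormley P	2016	ARMS2	rs2223089	C vs. G	0.93	0.91	0.95	3.0E-08	gwas	Caucasian 22	overall	59674	316078	22	0.1288	0.9098027819	
Gormley P	2016	IGSF9B	rs561561	T vs. A	0.94	0.92	0.96	3.4E-08	gwas	Caucasian 22	overall	59674	316078	22	0.0827	0.4986744225	
Gormley P	2016	NOTCH4	rs140002913	A vs. G	0.91	0.88	0.94	3.8E-08	gwas	Caucasian 22	overall	59674	316078	22	0.1150	1.0458242813	
Anttila V.	2013	PRDM16	rs2651899	C vs. T	1.09	1.07	1.12	3.28E-14	gwas	Caucasian 19	overall	23285	95425	19	0.4708	4.0649595346	
Anttila V.	2013	TSPAN2	rs12134493	A vs. C	1.14	1.10	1.18	6.71E-14	gwas	Caucasian 19	overall	23285	95425	19	0.0709	0.9828442876	
Anttila V.	2013	MEF2D	rs2274316	C vs. A	1.07	1.04	1.09	3.14E-08	gwas	Caucasian 19	overall	23285	95425	19	0.4289	2.9147892814	
Anttila V.	2013	TRPM8	rs7577262	A vs. G	0.87	0.84	0.90	3.27E-13	gwas	Caucasian 19	overall	23285	95425	19	0.2356	3.1595713513	
Anttila V.	2013	FHL5	rs13208321	A vs. T	1.18	1.13	1.24	2.15E-12	gwas	Caucasian 19	overall	23285	95425	19	0.2949	5.0406331131	
Anttila V.	2013	c7orf10	rs4379368	T vs. C	1.11	1.08	1.15	1.46E-09	gwas	Caucasian 19	overall	23285	95425	19	0.1961	2.1115517179	
Anttila V.	2013	MTDH	rs1835740	C vs. T	1.18	1.13	1.24	1.60E-11	gwas	Caucasian 7	overall	5950	50809	7	0.3510	5.9425497094	
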