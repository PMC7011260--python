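author	year	gene	variant	comparison	odds_ratio	ci_lower	ci_upper	p_value	study_type	ethnicity	subtype	n_cases	n_controls	n_studies	fprp_1.2_0.001	fprp_1.2_1e-06	fprp_1.5_0.001	fprp_1.5_1e-06	bfdp_0.001	bfdp_1e-06
Gormley P	2016	LRP1	rs11172113	C vs. T	0.85	0.82	0.89	4.3E-16	gwas	Overall	MO	8348	139622		5.365E-09	5.370E-06	4.295E-09	4.300E-06	4.578E-07	4.580E-04
Gormley P	2016	FHL5	rs7775721	T vs. A	1.15	1.11	1.20	1.1E-12	gwas	Overall	MO	8348	139622		1.253E-07	1.254E-04	1.222E-07	1.223E-04	1.210E-05	0.012
Gormley P	2016	ASTN2	rs6478241	G vs. A	1.14	1.09	1.18	1.2E-10	gwas	Overall	MO	8348	139622		9.555E-11	9.565E-08	9.538E-11	9.548E-08	1.305E-08	1.307E-05
Gormley P	2016	TRPM8	rs6724624	G vs. C	0.86	0.82	0.90	1.1E-09	gwas	Overall	MO	8348	139622		8.654E-08	8.662E-05	7.899E-08	7.906E-05	7.681E-06	7.630E-03
Gormley P	2016	PHACTR1	rs9349379	G vs. A	0.88	0.85	0.92	2.1E-09	gwas	Overall	MO	8348	139622		1.748E-05	0.017	1.733E-05	0.017	1.395E-03	0.583
Gormley P	2016	FGF6	rs1024905	A vs. G	1.12	1.08	1.16	2.5E-09	gwas	Overall	MO	8348	139622		2.451E-07	2.453E-04	2.451E-07	2.453E-04	2.680E-05	0.026
Gormley P	2016	TSPAN2	rs2078371	C vs. T	1.18	1.12	1.25	7.4E-09	gwas	Overall	MO	8348	139622		2.525E-05	0.025	1.808E-05	0.018	1.276E-03	0.561
Anttila V	2013	TRPM8	rs6741751	A vs. G	0.80	0.75	0.86	8.64E-11	gwas	Overall	MO	7107	69427		1.094E-05	0.011	1.469E-06	1.469E-03	1.143E-04	0.103
Anttila V	2013	LRP1	rs11172113	C vs. T	0.87	0.84	0.91	9.96E-11	gwas	Overall	MO	7107	69427		1.300E-06	1.300E-03	1.260E-06	1.260E-03	1.117E-04	0.101
Anttila V	2013	PHACTR1	rs9349379	G vs. A	0.86	0.82	0.90	2.81E-10	gwas	Overall	MO	7107	69427		8.654E-08	8.662E-05	7.899E-08	7.906E-05	7.681E-06	7.630E-03
Anttila V	2013	FHL5	rs11759769	A vs. G	1.18	1.13	1.24	1.58E-12	gwas	Overall	MO	7107	69427		8.181E-08	8.189E-05	6.109E-08	6.115E-05	5.781E-06	5.753E-03
Anttila V	2013	MMP16	rs10504861	T vs. C	0.86	0.81	0.90	1.17E-08	gwas	Overall	MO	7107	69427		8.654E-08	8.662E-05	7.899E-08	7.906E-05	7.681E-06	7.630E-03
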