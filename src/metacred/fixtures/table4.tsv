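author	year	gene	variant	comparison	odds_ratio	ci_lower	ci_upper	p_value	study_type	ethnicity	subtype	n_cases	n_controls	n_studies	fprp_1.2_0.05	fprp_1.2_0.001	fprp_1.5_0.05	fprp_1.5_0.001	bfdp_0.05	bfdp_0.001
Liu L	2019	MTHFR	rs1801133	T vs. C	1.18	1.04	1.34	0.012	observational	Caucasian 20	overall	9635	27592		0.253	0.947	0.169	0.915	0.766	0.994
Liu L	2019	MTHFR	rs1801133	TT vs. CT + CC	1.25	1.02	1.53	0.035	observational	Caucasian 20	overall	9635	27592		0.626	0.989	0.376	0.969	0.867	0.997
Liu L	2019	MTHFR	rs1801133	TT vs. CC	1.28	1.02	1.60	0.036	observational	Caucasian 20	overall	9635	27592		0.667	0.991	0.384	0.968	0.886	0.997
Dong H	2018	eNOS	rs2070744	CC vs. TC + TT	1.62	1.03	2.56	0.04	observational	Caucasian 4	overall	435	344		0.881	0.997	0.665	0.991	0.908	0.998
Terrazzino S	2017	BDNF	rs6265	A vs. G	1.17	1.03	1.34	0.014	observational	Caucasian 5	overall	2884	3760		0.408	0.973	0.307	0.959	0.856	0.997
Terrazzino S	2017	BDNF	rs6265	AA + GA vs. GG	1.22	1.05	1.41	0.011	observational	Caucasian 5	overall	2884	3760		0.247	0.945	0.119	0.877	0.694	0.992
Cai X	2017	BDNF	rs2049046	A vs. T	0.88	0.79	0.98	0.02	observational	Caucasian 4	overall	1260	1380		0.311	0.960	0.275	0.952	0.855	0.997
Cai X	2017	BDNF	rs2049046	AA vs. TA + TT	0.80	0.67	0.96	0.02	observational	Caucasian 4	overall	1260	1380		0.486	0.980	0.243	0.944	0.809	0.996
Cai X	2017	BDNF	rs2049046	AA vs. TT	0.78	0.62	0.97	0.02	observational	Caucasian 4	overall	1260	1380		0.637	0.989	0.345	0.965	0.853	0.997
Cai X	2017	BDNF	rs2049046	AA vs. TA	0.81	0.67	0.99	0.03	observational	Caucasian 4	overall	1260	1380		0.658	0.990	0.436	0.976	0.887	0.976
Li L	2015	ESR1	rs1801132	GG vs. CC	1.63	1.20	2.22	0.002	observational	Caucasian 4	overall	1693	1719		0.586	0.987	0.110	0.866	0.600	0.988
Li L	2015	ESR1	rs1801132	GG vs. CG + CC	1.63	1.21	2.21	0.001	observational	Caucasian 4	overall	1693	1719		0.564	0.986	0.096	0.848	0.572	0.986
Li L	2015	ESR1	rs2228480	AG vs. GG	1.19	1.04	1.35	0.009	observational	Caucasian 5	overall	1959	1826		0.192	0.926	0.116	0.873	0.696	0.992
Li L	2015	ESR1	rs2228480	AA + AG vs. GG	1.17	1.04	1.33	0.016	observational	Caucasian 5	overall	1959	1826		0.323	0.962	0.237	0.942	0.821	0.996
Chen M	2015	TNF-α	rs1800629	A vs. G	1.74	1.13	2.67	0.012	observational	Non-Caucasian 5	overall	985	956		0.828	0.996	0.462	0.978	0.851	0.997
Chen M	2015	TNF-α	rs1800629	AA+GA vs. GG	1.82	1.15	2.87	0.010	observational	Non-Caucasian 5	overall	985	956		0.838	0.996	0.483	0.980	0.854	0.997
Chen M	2015	TNF-α	rs1800629	GA vs. GG	1.78	1.17	2.72	0.007	observational	Non-Caucasian 5	overall	985	956		0.810	0.996	0.405	0.973	0.828	0.996
Chen M	2015	NOS3	rs1799983	TT vs. GT + GG	1.84	1.02	3.33	0.043	observational	Non-Caucasian 3	overall	504	339		0.914	0.998	0.770	0.994	0.923	0.998
Chen M	2015	NOS3	rs1799983	TT vs. GG	2.10	1.14	3.88	0.018	observational	Non-Caucasian 3	overall	504	339		0.902	0.998	0.706	0.992	0.907	0.998
Liu R	2014	TNF-β	rs909253	GG vs. AG + AA	1.38	1.04	1.84	0.027	observational	Non-Caucasian 3	overall	746	717		0.759	0.994	0.428	0.975	0.869	0.997
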