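author	year	gene	variant	comparison	odds_ratio	ci_lower	ci_upper	p_value	study_type	ethnicity	subtype	n_cases	n_controls	n_studies	venice_grades	venice_credibility	fprp_1.2_0.05	fprp_1.2_0.001	fprp_1.5_0.05	fprp_1.5_0.001	bfdp_0.05	bfdp_0.001
Liu L	2019	MTHFR	rs1801133	T vs. C	1.19	1.06	1.33	0.004	observational	Overall 26 (Caucasian 20, Asian 6)	overall	10228	28608	26	A + C + C	Low	0.069	0.795	0.040	0.685	0.476	0.980
Liu L	2019	MTHFR	rs1801133	TT vs. CT + CC	1.29	1.06	1.56	0.010	observational	Overall 26 (Caucasian 20, Asian 6)	overall	10228	28608	26	A + C + C	Low	0.419	0.974	0.149	0.902	0.726	0.993
Liu L	2019	MTHFR	rs1801133	TT + CT vs. CC	1.17	1.02	1.35	0.027	observational	Overall 26 (Caucasian 20, Asian 6)	overall	10228	28608	26	A + C + C	Low	0.485	0.980	0.375	0.969	0.880	0.997
Liu L	2019	MTHFR	rs1801133	TT vs. CC	1.32	1.07	1.64	0.011	observational	Overall 26 (Caucasian 20, Asian 6)	overall	10228	28608	26	A + C + C	Low	0.543	0.984	0.209	0.933	0.778	0.995
Liu L	2019	MTHFR	rs1801131	CC vs. AC + AA	1.82	1.09	3.04	0.022	observational	Overall 5 (Caucasian 4, Asian 1)	overall	1368	1411	5	A + C + C	Low	0.883	0.998	0.647	0.990	0.899	0.998
Liu L	2019	MTHFR	rs1801131	CC vs. AA	1.78	1.03	3.07	0.038	observational	Overall 5 (Caucasian 4, Asian 1)	overall	1368	1411	5	A + C + C	Low	0.903	0.998	0.729	0.993	0.917	0.998
Gao X	2018	GRIA1	rs2195450	CT vs. CC	1.23	1.02	1.48	0.03	observational	Overall 4 (Caucasian 3, Asian 1)	overall	963	1167	4	A + B + A	Intermediate	0.576	0.986	0.354	0.966	0.862	0.997
Terrazzino S	2017	BDNF	rs6265	A vs. G	1.17	1.03	1.34	0.014	observational	Overall 5 (Caucasian 5)	overall	2884	3760	5	A + A + A	High	0.408	0.973	0.307	0.959	0.856	0.997
Terrazzino S	2017	BDNF	rs6265	AA + GA vs. GG	1.22	1.05	1.41	0.011	observational	Overall 5 (Caucasian 5)	overall	2884	3760	5	A + A + A	High	0.247	0.945	0.119	0.877	0.694	0.992
Cai X	2017	BDNF	rs2049046	A vs. T	0.88	0.79	0.98	0.02	observational	Overall 4 (Caucasian 4)	overall	1260	1380	4	A + A + C	Low	0.311	0.960	0.275	0.952	0.855	0.997
Cai X	2017	BDNF	rs2049046	AA vs. TA + TT	0.80	0.67	0.96	0.02	observational	Overall 4 (Caucasian 4)	overall	1260	1380	4	A + A + A	High	0.486	0.980	0.243	0.944	0.809	0.996
Cai X	2017	BDNF	rs2049046	AA vs. TT	0.78	0.62	0.97	0.02	observational	Overall 4 (Caucasian 4)	overall	1260	1380	4	A + A + A	High	0.637	0.989	0.345	0.965	0.853	0.997
Cai X	2017	BDNF	rs2049046	AA vs. TA	0.81	0.67	0.99	0.03	observational	Overall 4 (Caucasian 4)	overall	1260	1380	4	A + A + A	High	0.658	0.990	0.436	0.976	0.887	0.998
Li L	2015	ESR1	rs1801132	GG vs. CC	1.51	1.15	1.99	0.003	observational	Overall 5 (Caucasian 4, Asian 1)	overall	2027	1919	5	A + A + A	High	0.559	0.985	0.119	0.877	0.644	0.990
Li L	2015	ESR1	rs1801132	GG vs. CG + CC	1.52	1.16	1.98	0.002	observational	Overall 5 (Caucasian 4, Asian 1)	overall	2027	1919	5	A + B + A	Intermediate	0.477	0.980	0.073	0.805	0.542	0.984
Li L	2015	ESR1	rs2228480	AG vs. GG	1.14	1.01	1.28	0.030	observational	Overall 6 (Caucasian 5, Asian 1)	overall	2293	2026	6	A + A + A	High	0.385	0.971	0.336	0.964	0.877	0.997
Li L	2015	ESR1	rs2228480	AA + AG vs. GG	1.13	1.00	1.26	0.003	observational	Overall 6 (Caucasian 5, Asian 1)	overall	2293	2026	6	A + B + A	Intermediate	0.381	0.970	0.346	0.965	0.885	0.998
Liu H	2011	5-HTT	VNTR	Stin2.12 allele	1.34	1.09	1.64	0.006	observational	Overall 4 (Caucasian 3, Asian1)	overall	495	729	4	A + A + NA	NA	0.377	0.970	0.090	0.840	0.628	0.989
Liu H	2011	5-HTT	VNTR	12/12 genotype	1.55	1.17	2.05	0.002	observational	Overall 4 (Caucasian 3, Asian1)	overall	495	729	4	A + A + NA	NA	0.526	0.983	0.090	0.838	0.557	0.986
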