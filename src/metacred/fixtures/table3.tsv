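author	year	gene	variant	comparison	odds_ratio	ci_lower	ci_upper	p_value	study_type	ethnicity	subtype	n_cases	n_controls	n_studies	fprp_1.2_0.05	fprp_1.2_0.001	fprp_1.5_0.05	fprp_1.5_0.001	bfdp_0.05	bfdp_0.001
Liu L	2019	MTHFR	rs1801133	T vs. C	1.28	1.09	1.51	0.003	observational	Overall	MA	4313	28092		0.226	0.939	0.063	0.778	0.560	0.985
Liu L	2019	MTHFR	rs1801133	CT + TT vs. CC	1.20	1.00	1.44	0.049	observational	Overall	MA	4313	28092		0.655	0.990	0.489	0.981	0.904	0.998
Liu L	2019	MTHFR	rs1801133	TT vs. CT + CC	1.46	1.10	1.95	0.010	observational	Overall	MA	4313	28092		0.682	0.991	0.256	0.948	0.788	0.995
Liu L	2019	MTHFR	rs1801133	TT vs. CC	1.51	1.09	2.08	0.012	observational	Overall	MA	4313	28092		0.735	0.993	0.314	0.960	0.812	0.996
Terrazzino S	2017	BDNF	rs6265	GA + AA vs. GG	1.22	1.00	1.47	0.047	observational	Overall	MA	717	1593		0.617	0.988	0.413	0.974	0.882	0.997
Li L	2015	ESR1	rs1801132	GG vs. CC	1.59	1.17	2.15	0.003	observational	Overall	MA	1427	1919		0.593	0.987	0.123	0.880	0.632	0.989
Li L	2015	ESR1	rs1801132	GG vs. CG + CC	1.58	1.18	2.13	0.002	observational	Overall	MA	1427	1919		0.590	0.987	0.122	0.880	0.633	0.989
Chen M	2015	TNF-α	rs1800629	AA+GA vs. GG	1.17	1.05	1.30	0.004	observational	Overall	MA	1763	21837		0.089	0.837	0.062	0.777	0.582	0.987
Chen M	2015	TNF-α	rs1800629	A vs. G	1.13	1.03	1.24	0.010	observational	Overall	MA	1763	21837		0.173	0.917	0.159	0.908	0.783	0.995
Chen M	2015	TNF-α	rs1800629	GA vs. GG	1.17	1.05	1.31	0.005	observational	Overall	MA	1763	21837		0.115	0.906	0.110	0.866	0.694	0.992
Chen M	2015	NOS3	rs1799983	TT vs. GG	1.61	1.12	2.31	0.010	observational	Overall	MA	440	881		0.770	0.994	0.345	0.965	0.816	0.996
Chen M	2015	NOS3	rs1799983	TT vs. GT + GG	1.50	1.08	2.09	0.016	observational	Overall	MA	440	881		0.771	0.994	0.387	0.971	0.843	0.996
Liu H	2011	5-HTT	VNTR	12/other	1.33	1.01	1.75	0.042	observational	Overall	MA	176	629		0.774	0.994	0.496	0.981	0.891	0.998
Liu H	2011	5-HTT	VNTR	12/12 vs. 12/other +other	1.58	1.07	2.33	0.021	observational	Overall	MA	176	629		0.829	0.996	0.501	0.981	0.873	0.997
Schurks M	2010	ACE	rs1799752	II vs. ID + DD	0.71	0.55	0.93	0.011	observational	Overall	MA	1761	22310		0.667	0.991	0.266	0.950	0.801	0.995
Liu L	2019	MTHFR	rs1801131	C vs. A	1.43	1.06	1.92	0.018	observational	Overall	MO	159	1477		0.730	0.993	0.345	0.965	0.835	0.996
Liu L	2019	MTHFR	rs1801131	CC vs. AC + AA	2.74	1.46	5.14	0.002	observational	Overall	MO	159	1477		0.864	0.997	0.515	0.982	0.842	0.996
Liu L	2019	MTHFR	rs1801131	CC vs. AA	2.83	1.30	6.16	0.009	observational	Overall	MO	159	1477		0.916	0.998	0.752	0.994	0.991	0.998
Liu H	2011	5-HTT	VNTR	12/other	1.30	1.02	1.67	0.037	observational	Overall	MO	319	697		0.741	0.993	0.467	0.979	0.887	0.998
Liu H	2011	5-HTT	VNTR	12/12 vs. 12/other +other	1.55	1.11	2.16	0.010	observational	Overall	MO	319	697		0.737	0.993	0.302	0.958	0.801	0.995
Schurks M	2010	ACE	rs1799752	II vs. ID + DD	0.84	0.70	0.99	0.049	observational	Overall	MO	2853	22310		0.570	0.986	0.417	0.974	0.888	0.998
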