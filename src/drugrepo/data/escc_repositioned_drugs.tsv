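drug	study	z_score	jaccard	odds_ratio	adj_p	within_species_rank
Erlotinib	In Vitro	-8.806362317	0.0159	21.6	5.66e-05	0.956
Palbociclib	In Vitro	-8.090451972	0.0156	21.1	6.18e-05	0.953
Doxorubicin	In Vitro	-7.851164741	0.0341	53.5	5.13e-09	0.993
Methotrexate	PharmOmics meta	-7.504929239	0.0135	18.3	7.80e-04	0.930
Crizotinib	In Vitro	-7.50277149	0.0208	29.5	1.61e-06	0.980
Vinblastine	PharmOmics meta	-6.871294272	0.0514	90.4	2.10e-17	0.998
Gemcitabine	In Vitro	-5.585120295	0.0243	35.8	3.91e-10	0.987
Daunorubicin	In Vitro	-5.155171903	0.0294	45.3	2.07e-07	0.991
Venlafaxine	In Vitro	-5.053770712	0.0153	20.7	6.74e-05	0.950
Ethanol	PharmOmics meta	-4.264304125	0.0233	34.1	5.61e-10	0.985
Tamoxifen	PharmOmics meta	-4.072907051	0.0179	25.1	3.24e-05	0.969
Arsenic trioxide	PharmOmics meta	-3.980019706	0.0467	79.5	2.10e-11	0.997
Dasatinib	In Vitro	-3.747277559	0.0208	29.5	1.61e-06	0.980
Ixazomib	PharmOmics meta	-3.730099165	0.0573	107.0	5.33e-21	0.999
Penicillamine	PharmOmics meta	-3.248848376	0.0413	67.5	1.53e-13	0.996
Nefazodone	In Vitro	-3.176922914	0.0115	15.1	1.35e-03	0.893
Leflunomide	PharmOmics meta	-2.888272698	0.0465	79.1	1.83e-15	0.997
Fulvestrant	In Vitro	-2.792994137	0.0235	34.1	8.07e-07	0.985
Azithromycin	In Vitro	-2.53558291	0.0279	41.6	2.17e-08	0.990
Hydrocortisone	PharmOmics meta	-2.37861135	0.0320	48.9	5.37e-10	0.992
Etanercept	PharmOmics meta	-2.333538798	0.0150	23.2	3.88e-03	0.948
Acetaminophen	PharmOmics meta	-2.196753074	0.0365	59.0	2.93e-14	0.994
Lapatinib	In Vitro	-2.141804897	0.0263	39.3	4.09e-07	0.989
Niacin	PharmOmics meta	-2.092485943	0.0225	32.4	1.03e-06	0.983
Anastrozole	PharmOmics meta	-2.073331977	0.0375	60.8	2.19e-14	0.994
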