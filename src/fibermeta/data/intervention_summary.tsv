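intervention_id	study_id	n_samples	n_subjects	rarefaction_depth	alpha_direction	alpha_significant	alpha_metrics	subject_r2_pct	subject_significant	fiber_r2_pct	fiber_significant
Baxter_2019_V4_himaize	Baxter_2019_V4	313	43	4891	down	True	both	86	True	0.2	True
Baxter_2019_V4_inulin	Baxter_2019_V4	365	50	4546	down	False	both	84	True	0.6	True
Baxter_2019_V4_potato	Baxter_2019_V4	273	43	4622	down	False	shannon	86	True	0.7	True
Dahl_2016_V1V2_potato-RS4A	Dahl_2016_V1V2	34	17	16289	down	False	both	89	True	1	True
Dahl_2016_V1V2_potato-RS4B	Dahl_2016_V1V2	36	18	15957	down	False	both	88	True	1	True
Dahl_2016_V1V2_potato-RS4C	Dahl_2016_V1V2	36	18	8135	down	False	both	87	True	0.8	False
Deehan_2020_V5V6_maize	Deehan_2020_V5V6	50	10	27488	down	True	both	87	True	1	True
Deehan_2020_V5V6_potato	Deehan_2020_V5V6	50	10	18744	down	False	both	85	True	0.5	False
Deehan_2020_V5V6_tapioca	Deehan_2020_V5V6	50	10	7157	down	True	both	79	True	1	True
Healey_2018_V3V4_inulin-FOS	Healey_2018_V3V4	68	34	6014	down	True	both	85	True	1.6	True
Hooda_2012_V4V6_corn	Hooda_2012_V4V6	19	10	3689	down	False	both	75	True	4.4	True
Hooda_2012_V4V6_polydextrose	Hooda_2012_V4V6	19	10	2966	up	False	both	76	True	4.6	True
Kovatcheva_2015_V1V2_bkb-bread	Kovatcheva_2015_V1V2	40	20	3642	down	False	both	86	True	0.6	False
Liu_2017_V4_FOS	Liu_2017_V4	66	34	1929	down	False	shannon	80	True	0.9	False
Liu_2017_V4_GOS	Liu_2017_V4	66	34	1465	down	False	both	78	True	1.5	True
Morales_2016_V3V4_oligofructose	Morales_2016_V3V4	22	11	66061	down	False	both	88	True	1.6	True
Rasmussen_2017_V1V3_SM12	Rasmussen_2017_V1V3	30	15	3217	down	False	both	74	True	1.6	False
Rasmussen_2017_V1V3_psyllium	Rasmussen_2017_V1V3	24	12	1197	down	False	both	76	True	2.6	False
Tap_2015_V3V4_dietary-fiber	Tap_2015_V3V4	38	19	1021	down	False	both	71	True	1.4	False
Vandeputte_2017_V4_inulin	Vandeputte_2017_V4	96	49	7912	down	True	both	83	True	0.7	True
Venkataraman_2016_V4_potato	Venkataraman_2016_V4	157	20	2167	down	False	shannon	84	True	0.9	True
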