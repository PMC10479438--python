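study_id	n_otus	n_significant_otus	n_large_effect_otus	n_positive_otus	n_negative_otus	tau_pos	tau_pos_significant	tau_neg	tau_neg_significant
Baxter_2019_V4	137	40	4	52	85	0.028	True	0.020	False
Healey_2018_V3V4	312	24	23	140	172	0.017	True	0.019	True
Hooda_2012_V4V6	208	23	23	115	93	0.018	False	0.020	True
Liu_2017_V4	86	12	12	31	55	0.019	False	0.029	False
Morales_2016_V3V4	1044	11	11	494	550	0.014	True	0.015	True
Tap_2015_V3V4	128	4	4	82	46	0.026	True	0.015	False
Vandeputte_2017_V4	463	22	22	136	327	0.016	True	0.021	True
Venkataraman_2016_V4	179	23	11	88	91	0.023	True	0.021	False
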