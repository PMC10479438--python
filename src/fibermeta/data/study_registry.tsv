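study_id	fiber_type	fiber_grams	duration_days	n_timepoints	n_subjects	n_samples
Baxter_2019_V4	resistant starch (potato, maize) and inulin	30	14	8	175	1205
Dahl_2016_V1V2	resistant potato starch (RS type 4)	30	14	4	53	212
Deehan_2020_V5V6	resistant starch (tapioca, potato, maize; RS type 4)	50	28	5	40	200
Healey_2018_V3V4	inulin / fructo-oligosaccharide blend	16	21	4	34	134
Hooda_2012_V4V6	polydextrose and soluble corn fiber	21	21	3	10	28
Kovatcheva_2015_V1V2	kernel-based bread vs white-wheat bread	37.6	3	3	20	60
Liu_2017_V4	fructo- and galacto-oligosaccharides	16	14	4	35	132
Morales_2016_V3V4	oligofructose	16	7	2	41	82
Rasmussen_2017_V1V3	starch-entrapped microspheres and psyllium	10.5	84	2	41	82
Tap_2015_V3V4	dietary fiber meals	25	5	4	19	76
Vandeputte_2017_V4	inulin	12	28	4	50	196
Venkataraman_2016_V4	resistant starch (unmodified potato starch; RS type 2)	48	17	8	20	157
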