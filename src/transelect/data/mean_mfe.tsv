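species	RankGT	GC%	GE	MeanMFE
Vibrio natriegens	1	42.8557	HEG	-4.2351
Vibrio cholerae	2	43.7813	HEG	-4.0721
Escherichia coli	3	46.5955	HEG	-4.2153
Bacillus subtilis	4	38.7556	HEG	-3.7484
Haemophilus influenzae	5	37.9329	HEG	-3.2660
Mycolicibacterium smegmatis	6	60.4224	HEG	-6.4462
Mycobacterioides abscessus	7	60.4048	HEG	-5.5966
Mycobacterium tuberculosis	8	61.5043	HEG	-6.2934
Mycobacterium leprae	9	56.5344	HEG	-5.7794
Vibrio natriegens	1	40.4234	REST	-3.5238
Vibrio cholerae	2	43.3125	REST	-4.0330
Escherichia coli	3	45.6418	REST	-4.4059
Bacillus subtilis	4	38.6014	REST	-3.7406
Haemophilus influenzae	5	33.7986	REST	-2.5466
Mycolicibacterium smegmatis	6	63.6954	REST	-8.6708
Mycobacterioides abscessus	7	61.2667	REST	-8.3538
Mycobacterium tuberculosis	8	63.0856	REST	-9.1141
Mycobacterium leprae	9	57.1858	REST	-7.9865
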