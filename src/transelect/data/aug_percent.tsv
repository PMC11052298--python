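species	AUG%	RankGT	GC%	GE
Vibrio natriegens	93.4211	1	45.0	HEG
Vibrio cholerae	92.1053	2	47.3	HEG
Escherichia coli	94.5205	3	50.8	HEG
Bacillus subtilis	87.8788	4	43.5	HEG
Haemophilus influenzae	97.1429	5	38.2	HEG
Mycolicibacterium smegmatis	75.0000	6	67.4	HEG
Mycobacterioides abscessus	77.9412	7	64.1	HEG
Mycobacterium tuberculosis	79.0323	8	65.6	HEG
Mycobacterium leprae	71.6418	9	57.8	HEG
Vibrio natriegens	90.1179	1	45.0	REST
Vibrio cholerae	88.7332	2	47.3	REST
Escherichia coli	90.0592	3	50.8	REST
Bacillus subtilis	77.3196	4	43.5	REST
Haemophilus influenzae	94.5831	5	38.2	REST
Mycolicibacterium smegmatis	65.8058	6	67.4	REST
Mycobacterioides abscessus	66.8103	7	64.1	REST
Mycobacterium tuberculosis	61.3163	8	65.6	REST
Mycobacterium leprae	51.3478	9	57.8	REST
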