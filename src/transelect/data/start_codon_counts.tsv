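species	RankGT	GC%	GE	AUG	GUG	YUG	AUH	N
Vibrio natriegens	1	45.0	HEG	71	3	2	0	76
Vibrio cholerae	2	47.3	HEG	70	3	3	0	76
Escherichia coli	3	50.8	HEG	69	3	1	0	73
Bacillus subtilis	4	43.5	HEG	58	5	3	0	66
Haemophilus influenzae	5	38.2	HEG	68	1	1	0	70
Mycolicibacterium smegmatis	6	67.4	HEG	54	18	0	0	72
Mycobacterioides abscessus	7	64.1	HEG	53	14	1	0	68
Mycobacterium tuberculosis	8	65.6	HEG	49	13	0	0	62
Mycobacterium leprae	9	57.8	HEG	48	16	3	0	67
Vibrio natriegens	1	45.0	REST	3976	297	124	15	4412
Vibrio cholerae	2	47.3	REST	3166	253	131	18	3568
Escherichia coli	3	50.8	REST	3805	335	81	4	4225
Bacillus subtilis	4	43.5	REST	3225	382	555	9	4171
Haemophilus influenzae	5	38.2	REST	1554	51	28	10	1643
Mycolicibacterium smegmatis	6	67.4	REST	4255	1998	187	26	6466
Mycobacterioides abscessus	7	64.1	REST	3255	1458	145	14	4872
Mycobacterium tuberculosis	8	65.6	REST	2357	1306	177	4	3844
Mycobacterium leprae	9	57.8	REST	1162	782	276	43	2263
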