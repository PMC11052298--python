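species	RankGT	N_AC	RankN_AC
Vibrio natriegens	1	40.2129	1
Vibrio cholerae	2	44.2802	2
Escherichia coli	3	49.0127	4
Bacillus subtilis	4	45.8531	3
Haemophilus influenzae	5	50.4305	5
Mycolicibacterium smegmatis	6	59.0667	7
Mycobacterioides abscessus	7	58.8153	6
Mycobacterium tuberculosis	8	59.3744	8.5
Mycobacterium leprae	9	59.3744	8.5
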