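species	RankGT	L_genome	N_CDS	N_rrn	N_tRNA
Vibrio natriegens	1	5175153	4496	11	129
Vibrio cholerae	2	4089299	3628	10	102
Escherichia coli	3	4641652	4298	7	86
Bacillus subtilis	4	4215606	4237	10	86
Haemophilus influenzae	5	1846259	1714	6	59
Mycolicibacterium smegmatis	6	6993871	6540	3	47
Mycobacterioides abscessus	7	5067231	4938	1	47
Mycobacterium tuberculosis	8	4411532	3905	1	45
Mycobacterium leprae	9	3187112	2328	1	45
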