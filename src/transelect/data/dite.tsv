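species	RankGT	DITE	RankDITE
Vibrio natriegens	1	0.2516	9
Vibrio cholerae	2	0.2380	6.5
Escherichia coli	3	0.2465	8
Bacillus subtilis	4	0.2380	6.5
Haemophilus influenzae	5	0.2092	5
Mycolicibacterium smegmatis	6	0.1266	3
Mycobacterioides abscessus	7	0.1806	4
Mycobacterium tuberculosis	8	0.0267	1
Mycobacterium leprae	9	0.0689	2
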