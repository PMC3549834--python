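protein_id	method	cys_a	cys_b	belief
1G6X	M1	5	55	0.99
1G6X	M1	14	38	0.91
1G6X	M1	31	51	0.86
1G6X	M1	14	31	0.01
1G6X	M2	5	38	0.91
1G6X	M2	51	55	0.89
1G6X	M2	14	31	0.01
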