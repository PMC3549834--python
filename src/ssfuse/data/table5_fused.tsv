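protein_id	method	cys_a	cys_b	belief
Q92187	shafer	142	292	0.66
Q92187	shafer	156	356	0.68
P02754	shafer	82	176	0.49
P02754	shafer	122	135	0.36
Q11130	shafer	68	76	0.43
Q11130	shafer	211	214	0.26
Q11130	shafer	318	321	0.54
P08037	shafer	134	176	0.35
P08037	shafer	247	266	0.36
Q09324	shafer	59	413	0.07
Q09324	shafer	100	172	0.08
Q09324	shafer	151	199	0.26
Q09324	shafer	372	381	0.06
P00698	shafer	24	145	0.31
P00698	shafer	48	133	0.13
P00698	shafer	82	98	0.10
P00698	shafer	94	112	0.10
P21217	shafer	81	338	0.67
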