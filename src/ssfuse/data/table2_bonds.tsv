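protein_id	method	cys_a	cys_b
Q92187	known	142	292
Q92187	known	156	356
P02754	known	82	176
P02754	known	122	135
Q11130	known	68	76
Q11130	known	211	214
Q11130	known	318	321
P08037	known	134	176
P08037	known	247	266
Q09324	known	59	413
Q09324	known	372	381
Q09324	known	100	172
Q09324	known	151	199
P00698	known	24	145
P00698	known	48	133
P21217	known	81	338
P21217	known	91	341
Q92187	MS2DB+	142	292
Q92187	MS2DB+	156	356
P02754	MS2DB+	82	176
Q11130	MS2DB+	68	76
Q11130	MS2DB+	211	214
Q11130	MS2DB+	318	321
P08037	MS2DB+	134	176
P08037	MS2DB+	247	266
Q09324	MS2DB+	59	413
Q09324	MS2DB+	372	381
Q09324	MS2DB+	151	199
P00698	MS2DB+	24	145
P00698	MS2DB+	48	133
P21217	MS2DB+	81	338
Q92187	SVM	142	292
Q92187	SVM	156	356
P02754	SVM	122	135
P02754	SVM	137	176
Q11130	SVM	68	76
Q11130	SVM	211	214
Q11130	SVM	318	321
P08037	SVM	134	247
Q09324	SVM	372	381
Q09324	SVM	100	172
Q09324	SVM	199	235
P00698	SVM	24	145
P21217	SVM	81	91
P21217	SVM	338	341
Q92187	CSP	142	292
Q92187	CSP	156	356
P02754	CSP	122	135
P02754	CSP	137	176
Q11130	CSP	68	76
Q11130	CSP	211	214
Q11130	CSP	318	321
P08037	CSP	134	176
P08037	CSP	247	266
Q09324	CSP	151	217
Q09324	CSP	172	199
Q09324	CSP	59	100
P00698	CSP	82	98
P00698	CSP	94	112
P21217	CSP	81	91
P21217	CSP	338	341
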