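protein_id	method	cys_a	cys_b
Q92187	massmatrix	142	292
Q92187	massmatrix	156	356
P02754	massmatrix	82	176
Q11130	massmatrix	68	76
Q11130	massmatrix	211	214
Q11130	massmatrix	318	321
P08037	massmatrix	134	176
P08037	massmatrix	247	266
P00698	massmatrix	48	133
Q92187	dempster_campos_shafer	142	292
Q92187	dempster_campos_shafer	156	356
P02754	dempster_campos_shafer	82	176
P02754	dempster_campos_shafer	122	135
Q11130	dempster_campos_shafer	68	76
Q11130	dempster_campos_shafer	211	214
Q11130	dempster_campos_shafer	318	321
P08037	dempster_campos_shafer	134	176
P08037	dempster_campos_shafer	247	266
Q09324	dempster_campos_shafer	372	381
P00698	dempster_campos_shafer	24	145
P00698	dempster_campos_shafer	48	133
Q92187	yager	142	292
Q92187	yager	156	356
P02754	yager	82	176
P02754	yager	122	135
Q11130	yager	68	76
Q11130	yager	211	214
Q11130	yager	318	321
Q09324	yager	372	381
P00698	yager	24	145
P00698	yager	48	133
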