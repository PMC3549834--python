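protein_id	method	cys_a	cys_b	belief
P08037	MS	134	176	0.80
P08037	MS	247	266	0.81
P08037	SVM	134	247	0.96
P08037	CSP	134	176	0.21
P08037	CSP	247	266	0.21
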