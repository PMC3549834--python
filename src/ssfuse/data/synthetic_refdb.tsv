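protein_id	cys_positions	bonds
REF01	10,25,40,60	1-3,2-4
REF02	12,26,44,58	1-4,2-3
REF03	8,50,70,95	1-2,3-4
REF04	5,14,31,38,51,55	1-6,2-4,3-5
REF05	10,16,23,36,49,53	1-3,2-5,4-6
REF06	7,30,42,66,80,90	1-4,2-6,3-5
REF07	5,20,35,50,65,80,95,110	1-5,2-6,3-7,4-8
REF08	9,18,27,45,60,72,85,99	1-2,3-4,5-6,7-8
REF09	15,24,41,48,61,66	1-6,2-4,3-5
REF10	20,33,47,71	1-3,2-4
REF11	11,22,50,61,74,88	1-5,2-3,4-6
REF12	6,19,33,47,62,76,91,105	1-8,2-7,3-6,4-5
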