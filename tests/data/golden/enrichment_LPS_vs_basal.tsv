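term_id	term_name	k	K	n	N	odds_ratio	p	q	significant	direction	signed_score
CC:Golgi_apparatus	Golgi apparatus	0	10	2	48	0.695238	1	1	False	up	-0
CC:endoplasmic_reticulum	endoplasmic reticulum	0	8	2	48	0.905882	1	1	False	up	-0
CC:extracellular_region	extracellular region	1	9	2	48	4.75	0.343085	1	False	up	-0
CC:lysosome	lysosome	0	9	2	48	0.789474	1	1	False	up	-0
CC:plasma_membrane	plasma membrane	1	12	2	48	3.18182	0.441489	1	False	up	-0
CC:Golgi_apparatus	Golgi apparatus	1	10	8	48	0.492063	0.870402	0.870402	False	down	-0.0602799
CC:endoplasmic_reticulum	endoplasmic reticulum	2	8	8	48	1.88889	0.400944	0.870402	False	down	-0.0602799
CC:extracellular_region	extracellular region	1	9	8	48	0.571429	0.836958	0.870402	False	down	-0.0602799
CC:lysosome	lysosome	2	9	8	48	1.57143	0.470113	0.870402	False	down	-0.0602799
CC:plasma_membrane	plasma membrane	2	12	8	48	1	0.654345	0.870402	False	down	-0.0602799
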