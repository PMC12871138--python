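term_id	term_name	k	K	n	N	odds_ratio	p	q	significant	direction	signed_score
CC:Golgi_apparatus	Golgi apparatus	0	10	2	49	0.714286	1	1	False	up	-0
CC:endoplasmic_reticulum	endoplasmic reticulum	0	8	2	49	0.929412	1	1	False	up	-0
CC:extracellular_region	extracellular region	1	10	2	49	4.22222	0.369898	1	False	up	-0
CC:lysosome	lysosome	0	9	2	49	0.810526	1	1	False	up	-0
CC:plasma_membrane	plasma membrane	1	12	2	49	3.27273	0.433673	1	False	up	-0
CC:Golgi_apparatus	Golgi apparatus	0	10	2	49	0.714286	1	1	False	down	0
CC:endoplasmic_reticulum	endoplasmic reticulum	0	8	2	49	0.929412	1	1	False	down	0
CC:extracellular_region	extracellular region	1	10	2	49	4.22222	0.369898	1	False	down	0
CC:lysosome	lysosome	0	9	2	49	0.810526	1	1	False	down	0
CC:plasma_membrane	plasma membrane	1	12	2	49	3.27273	0.433673	1	False	down	0
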