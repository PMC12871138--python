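protein	disease	chapter	odds_ratio	p_adj	cohort_n
SYUG	type_2_diabetes	endocrine	1.64	3.66e-31	53026
SYUG	hypercholesterolemia	endocrine	1.3	6.64e-14	53026
SYUG	lipoprotein_metabolism_disorder	endocrine	1.3	8.93e-15	53026
SYUG	heart_failure	circulatory	1.95	1.83e-22	53026
SERPINF1	type_2_diabetes	endocrine	4.5	3.47e-40	53026
APOA4	type_2_diabetes	endocrine	3.23	1.23e-76	53026
LEP	hypertension	circulatory	1.4	1.84e-47	53026
LEP	metabolic_disorder	endocrine	1.5	6.9e-39	53026
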