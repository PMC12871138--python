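protein	cc_terms	signal_peptide	ups_predicted	transmembrane	tissue_enriched	concentration	concentration_unit
ALBU	extracellular region	true	false	false	liver	137.3	nmol/mL
APOA1	extracellular region	true	false	false	liver	47.5	nmol/mL
FIBG	extracellular region	true	false	false	liver	9.3	nmol/mL
CFD	extracellular region	true	false	false	adipose	67.2	pmol/mL
LRP1	plasma membrane	false	false	true	adipose	7.8	pmol/mL
PLSL	extracellular region	false	true	false		1.4	pmol/mL
FGL1	extracellular region	true	false	false	liver	0.8	pmol/mL
TSP4	extracellular region	true	false	false		0.7	pmol/mL
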