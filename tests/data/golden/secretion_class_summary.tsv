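secretion_class	count	fraction
signal_peptide	41	0.82
ups_predicted	3	0.06
transmembrane_only	0	0
intracellular_other	6	0.12
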