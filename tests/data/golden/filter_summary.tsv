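plex_id	n_identified	n_passing	selected_cutoff	selected_j	auc
plex1	100	50	-0.380826	1	1
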