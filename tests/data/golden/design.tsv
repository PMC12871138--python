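channel_id	genotype	condition	tissue	replicate	plex_id
plex1_basal_pos1	cre_pos	basal	iWAT	1	plex1
plex1_basal_pos2	cre_pos	basal	iWAT	2	plex1
plex1_basal_pos3	cre_pos	basal	iWAT	3	plex1
plex1_basal_neg1	cre_neg	basal	iWAT	1	plex1
plex1_basal_neg2	cre_neg	basal	iWAT	2	plex1
plex1_basal_neg3	cre_neg	basal	iWAT	3	plex1
plex1_LPS_pos1	cre_pos	LPS	iWAT	1	plex1
plex1_LPS_pos2	cre_pos	LPS	iWAT	2	plex1
plex1_LPS_pos3	cre_pos	LPS	iWAT	3	plex1
plex1_LPS_neg1	cre_neg	LPS	iWAT	1	plex1
plex1_LPS_neg2	cre_neg	LPS	iWAT	2	plex1
plex1_fasted_pos1	cre_pos	fasted	iWAT	1	plex1
plex1_fasted_pos2	cre_pos	fasted	iWAT	2	plex1
plex1_fasted_pos3	cre_pos	fasted	iWAT	3	plex1
plex1_fasted_neg1	cre_neg	fasted	iWAT	1	plex1
plex1_fasted_neg2	cre_neg	fasted	iWAT	2	plex1
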