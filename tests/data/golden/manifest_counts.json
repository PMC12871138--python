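{
  "n_channels": 16,
  "n_enriched_terms_LPS_vs_basal": 0,
  "n_enriched_terms_fasted_vs_basal": 0,
  "n_passing": 50,
  "n_proteins": 100,
  "n_signal_peptide": 41,
  "n_significant_down_LPS_vs_basal": 8,
  "n_significant_down_fasted_vs_basal": 2,
  "n_significant_up_LPS_vs_basal": 2,
  "n_significant_up_fasted_vs_basal": 2
}
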