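mode: simulate
sim:
  n_proteins: 100
  frac_secretory: 0.5
  frac_background: 0.3
  seed: 0
seed: 17
out_dir: golden_run
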