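# Full-pipeline configuration: a small synthetic cohort with one planted
# quadratic coupling, analysed with PCC and eMIC for the CN-MCI contrast.
seed: 7
out_dir: scratch/example_run
methods: [pcc, emic]
contrasts: [[1, 2]]
selection_fraction: 0.01
classifier:
  c: 1.0
  scaling: zscore
synthetic:
  n_regions: 12
  n_timepoints: 128
  group_sizes: [8, 8, 4]
  noise_sd: 0.3
  couplings:
    - pair: [0, 1]
      transfer: quadratic
      strength: [1.0, 0.0, 0.5]
    - pair: [2, 3]
      transfer: sine
      strength: [1.0, 0.0, 0.5]
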