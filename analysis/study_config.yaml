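# Study-scale synthetic cohort: 794 participants, 8 views (one ordinal
# clinical view with skip-rule sections + 7 continuous imaging views), two
# planted sparse components at a brain-behavior-typical effect size.
output_dir: results/study
simulate:
  n_participants: 794
  n_true_components: 2
  support_fraction: 0.05
  loading_scale: 0.4
  noise_sd: 1.0
  seed: 20260921
split:
  fraction: 0.7
  seed: 101
tuning:
  grid: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
  n_perm: 100
  seed: 102
components:
  k_max: 6
  epsilon: 0.01
stability:
  n_subsamples: 200
  fraction: 0.5
  threshold: 0.9
  seed: 103
inference:
  n_perm: 200
  n_boot: 1000
  seed: 104
verbosity: 1
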