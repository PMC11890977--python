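# Full synthetic study at the emulated design scale.
# Reduce n_hc/n_vci or null_count for a quick smoke run.
seed: 1

simulate:
  n_nodes: 90
  n_hc: 53
  n_vci: 68
  n_timepoints: 200
  backbone_k: 16
  backbone_p: 0.1
  count_scale: 12.0
  vci_structural_deficit: 0.3
  coupling_base: 0.35
  coupling_boost: 0.3
  cognition_effect: -30.0
  noise_sd: 7.0

analysis:
  fiber_threshold: 3
  group_consistency: 0.8
  consistency_scope: all        # or per_group
  sparsity_grid: [0.01, 0.40, 0.01]
  null_count: 100
  swaps_per_edge: 10
  permutations: 1000
  alpha: 0.05
  fwe_method: permutation_maxT  # or bonferroni
  coupling_sc_weighting: count  # or binary
  coupling_selection: sc_nonzero
  min_coupling_pairs: 10
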