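# Desk-scale demo run: every stage of the hybrid-breeding pipeline on a
# small simulated population.  Two runs with the same seed are
# byte-identical.
seed: 11
simulation:
  n_chromosomes: 2
  markers_per_chromosome: 500
  chrom_length_cm: 120.0
  diff_fraction: 0.6
  purity: 0.95
  n_indica: 19
  n_japonica: 23
scan:
  window: 199
  step: 1
  min_hits: 120
  min_indica: 17
  min_japonica: 21
training:
  n_hybrids: 400
  n_qtl_per_trait: 15
  heritability: 0.5
gblup:
  use_dominance: false
  k_folds: 6
  iterations: 1
index:
  n_females: 12
  n_males: 8
pve:
  span_bp: 1000000
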