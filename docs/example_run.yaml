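# Full-pipeline configuration for `dnbpipe run-all --config docs/example_run.yaml`.
# Omitted keys take the defaults documented in dnbpipe.pipeline.RunConfig.
output_dir: dnbpipe_out
seed: 1
synthetic:            # drop this block and set expression_path/annotation_path
  n_proteins: 2000    # to analyze your own cohort instead
  seed: 1
compartment: L
min_frac_complete: 0.5
alpha: 0.05
fc_hi: 1.20
fc_lo: 0.83
n_clusters: 4
fuzzifier: 1.25
dnb_min_module_size: 5
dnb_linkage_cut: 0.5
permutations: 0       # set 99 for per-stage permutation p-values
panel_k: 7
panel_folds: 5
crosstalk_stage: MOD
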