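# Full pipeline run on a synthetic cohort at the study's scale.
# Reproduce with: adcascade run --config configs/example_run.yaml
outdir: results/run_example
synthetic:
  seed: 7
  n_ds: 348
  n_controls: 42
compare_biomarkers: [gfap, ptau217]
trajectory_biomarkers: [centiloid, ptau217, gfap, tau_suvr]
trajectory_bootstrap: 2000
trajectory_seed: 7
mediation_outcomes: [tau_suvr, ptau217]
mediation_bootstrap: 2000
mediation_seed: 11
grid_step: 0.1
ci_level: 0.95
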