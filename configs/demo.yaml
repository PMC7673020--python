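# Demonstration run: simulate a 219-line RIL population (12 chromosomes,
# 1500 markers, one additive QTL explaining 19% of trait variance), mask 5%
# of calls, impute them back, run the mixed-model scan at the 1e-6
# genome-wide threshold, and scan a simulated diversity panel for sweeps.
seed: 1
out_dir: results/demo
stages: [simulate, impute, assoc, sweep]
simulate:
  n_lines: 219
  pve_qtl: 0.19
  missing_rate: 0.05
assoc:
  p_threshold: 1e-6
sweep:
  window_bp: 100000
  step_bp: 10000
  quantile: 0.95
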