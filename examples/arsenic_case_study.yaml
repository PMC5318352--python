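# Packaged arsenic non-cancer risk run: `hybriduq run --config examples/arsenic_case_study.yaml`
# Equivalent to `hybriduq case-study` with its defaults.
model: arsenic_case_study
engine:
  n_mc: 5000
  seed: 20170131
  alpha_steps: 10
summaries:
  fractiles: [0.95, 0.85]
  range_percentiles: [0.005, 0.995]
  quantile_mode: analytic
out_dir: hybriduq_out
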