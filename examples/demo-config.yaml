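# Demo pipeline: synthesise a library and a sample/blank pair, annotate,
# and validate against the ground truth.
#   swath-annotator run --config examples/demo-config.yaml
seed: 7
out_dir: demo-run
library:
  n_compounds: 50
simulate:
  n_spike: 10
  run_length: 8.0
  rt_range: [3.0, 7.0]
params:
  ppm_tol: 10.0
  snr_min: 30.0
  screen_blank_ratio_min: 5.0
  filter_blank_ratio_min: 5.0
  frag_tol_da: 0.05
  rt_shift_max: 0.001417
  width_shift_max: 0.174965
  rel_int_min_pct: 5.0
validate: true
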