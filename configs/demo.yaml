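# Demo pipeline configuration: 30-cell cohort with voltage-clamp traces.
seed: 7
out_dir: demo_run
n_cells: 30
cohort:
  simulate_vc: true
  vc_schedule:
    - ["gaba", 0.0, 120.0]
    - ["bicuculline", 120.0, 260.0]
vc:
  cap_interval: 90.0
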