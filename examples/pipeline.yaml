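# Desk-scale end-to-end pipeline: simulate -> build-dataset -> train -> evaluate.
# Artifacts land in pipeline_out/; finished stages are skipped on re-run.
seed: 5
out_dir: pipeline_out
horizon: 100
params:
  lattice_size: 64
  n_cells_initial: 62
simulate:
  n_train_runs: 2
  n_eval_runs: 1
  mcs_start_save: 200
  mcs_end: 800
  save_every: 25
train:
  depth: 2
  base_channels: 8
  epochs: 10
  batch_size: 8
evaluate:
  t0_mcs: 600
  n_iterations: 2
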