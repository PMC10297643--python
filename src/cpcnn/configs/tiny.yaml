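# Desk-scale smoke configuration: a miniature end-to-end run that
# exercises phantom generation, two-stage training, cross-validation and
# report writing in well under a minute on one CPU.
seed: 0
output_dir: cpcnn_run
n_cases: 12
phantoms:
  base_resolution: [64, 32]
  lesion_probability: 0.5
cascade:
  base_size: [64, 32]
  width_multiplier: 0.25
  block_repeats: [1, 1, 1, 1]
  learning_rate: 0.05
  batch_size: 4
  epochs_primary: 2
  epochs_cascade: 1
evaluation:
  k: 2
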