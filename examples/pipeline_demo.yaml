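# Demo profile: reduced sizes, learning rate raised so the micro-width
# models converge within a handful of epochs.
seed: 0
out_dir: artifacts/pipeline_demo
stage1:
  n_train: 200
  n_val: 16
  epochs: 8
  learning_rate: 0.005
  finetune_epochs: 3
stage2:
  n_per_class: 24
  epochs: 30
  learning_rate: 0.003
  augment: true
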