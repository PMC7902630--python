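# Run configuration template for the autocascade CLI
# (autocascade train / crossval / compare --config run.yaml)

cascade:
  arch: unet            # unet | resunet | seunet
  depth: 2              # down-sampling steps; 4 for full-scale volumes
  base_filters: 8       # filters at the first level, doubling per level
  input_size: 64        # cubic grid edge; must be divisible by 2^depth
  axis_order: [coronal, sagittal, axial]
  threshold: 0.5
  connectivity: 26

train:
  learning_rate: 0.0001
  batch_size: 20
  max_epochs: 200
  early_stop_patience: 20
  seed: 0
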