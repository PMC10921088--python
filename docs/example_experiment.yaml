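# Example configuration for `watunet experiment --config ... --seed ... --out ...`
# Sections map one-to-one onto the library's config dataclasses; omitted
# fields keep their defaults.
phantom:
  n_samples: 200
  image_size: [64, 64]
  class_proportions: [0.5363, 0.2148, 0.2489]   # no_mass : benign : malignant
  lesion_area_range: [0.03, 0.15]
  lesion_contrast: 0.45
split:
  train_frac: 0.8
  val_frac: 0.1
  test_frac: 0.1
  stratify_by_class: true
train:
  epochs: 15
  batch_size: 8
network:
  depth: 4
  base_channels: 8
  input_size: [64, 64]
modes: [plain, attention, sharpen, watunet]
apply_clahe: true
clahe:
  clip_limit: 2.0
  tile_grid: [8, 8]
# augment:                      # uncomment to balance classes via augmentation
#   rotation_range: 15.0
#   zoom_range: [0.9, 1.1]
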