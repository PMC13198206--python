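augment:
  channel_brightness:
  - 0.9
  - 1.1
  crop_size: 256
  hflip_prob: 0.5
  rgb_brightness:
  - 0.9
  - 1.1
  rgb_contrast:
  - 0.9
  - 1.1
  rgb_saturation:
  - 0.9
  - 1.1
  rotation_degrees: 180.0
  vflip_prob: 0.5
batch_size: 64
contrastive_kind: triplet
contrastive_reduction: mean
encoder: resnet18
feature_dim: 512
iterations_per_epoch: 1000
labeled_per_class: 8
lambda_u_rampup_epochs: 16.0
learning_rate: 0.0001
lr_decay: 0.97
max_epochs: 10000
n_classes: 4
optimizer: rmsprop
patience_epochs: 100
seed: 0
use_adaptive_stains: true
use_contrastive: true
use_mixup: true
use_projection_heads: false
use_rgb_aug: true
view_mode: HE
weights:
  beta_alpha: 2.0
  k_augment: 2
  lambda_c: 0.1
  lambda_u: 7.5
  margin: 37.0
  temperature: 0.5
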