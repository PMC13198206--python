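# desk-scale simulator profile
n_slides: 10
n_labeled_per_class: 30
n_unlabeled: 300
n_val_per_class: 20
n_test_per_class: 20
tile_size: 64
noise_sd: 0.03
drift_deg: 10.0
n_labeled_slides: 2
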