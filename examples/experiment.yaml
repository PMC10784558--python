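# Full-protocol experiment: 5 storage-year classes, 100 samples each,
# 80/20 stratified split, both classifiers trained on identical streams.
n_per_class: 100
train_fraction: 0.8
test_fraction: 0.2
walsh_order: 8
noise_on_test: true
seed: 0

profiles:
  - {label: SW2015, mean_I0: 2907, mean_beta: 0.724, mean_tau: 4.47, rel_spread: 0.06}
  - {label: SW2016, mean_I0: 2837, mean_beta: 0.653, mean_tau: 4.46, rel_spread: 0.06}
  - {label: SW2017, mean_I0: 3080, mean_beta: 0.663, mean_tau: 4.58, rel_spread: 0.06}
  - {label: SW2018, mean_I0: 3434, mean_beta: 0.796, mean_tau: 3.08, rel_spread: 0.06}
  - {label: SW2019, mean_I0: 2876, mean_beta: 0.744, mean_tau: 5.63, rel_spread: 0.06}

acquisition:
  dt: 0.1            # seconds per bin
  total_time: 100.0  # 1000 bins per trace
  background: 9.0    # constant instrument background, counts per bin
  noise_mode: poisson

feature_config:
  kaiser_shape: 5.0
  apen_m: 2
  apen_r_factor: 0.2
  mean_center: true

train_config:
  batch_size: 8
  epochs: 100
  learning_rate: 5.0e-4
  hidden: 128
  l2_lambda: 1.0e-3
  feature_noise_sd: 0.1
  layout: sequence
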