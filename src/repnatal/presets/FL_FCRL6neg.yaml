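# Fetal liver FCRL6- pro B cells: Tdt off, light trimming (high productivity),
# proximal-leaning V usage, rare D-less joins, higher Y101.
subset_label: FL_FCRL6neg
n_clones: 4000
clone_size: {distribution: geometric, mean: 3.0}
tdt_on: false
n_insert_mean: 0.0
trim_mean_v3: 0.05
trim_mean_d5: 0.15
trim_mean_d3: 0.15
trim_mean_j5: 0.3
y101_target: 0.33
max_rejections: 5000
v_weights:
  Ighv5-2: 0.20
  Ighv2-3: 0.15
  Ighv7-1: 0.15
  Ighv14-2: 0.10
  Ighv12-3: 0.10
  Ighv11-2: 0.10
  Ighv1-26: 0.10
  Ighv1-55: 0.10
d_weights:
  Ighd1-1: 0.42
  Ighd2-3: 0.37
  Ighd4-1: 0.18
  D-less: 0.03
j_weights:
  Ighj1: 0.25
  Ighj2: 0.25
  Ighj3: 0.25
  Ighj4: 0.25
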