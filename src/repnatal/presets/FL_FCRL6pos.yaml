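# Fetal liver FCRL6+ pro B cells: Tdt off, heavy junctional trimming,
# distal (domain 4, J558-like) V bias, frequent D-less joins, low Y101.
subset_label: FL_FCRL6pos
n_clones: 4000
clone_size: {distribution: geometric, mean: 3.0}
tdt_on: false
n_insert_mean: 0.0
trim_mean_v3: 0.5
trim_mean_d5: 1.5
trim_mean_d3: 1.5
trim_mean_j5: 2.5
y101_target: 0.22
max_rejections: 5000
v_weights:
  Ighv1-26: 0.25
  Ighv1-55: 0.20
  Ighv11-2: 0.15
  Ighv12-3: 0.10
  Ighv5-2: 0.10
  Ighv2-3: 0.08
  Ighv7-1: 0.07
  Ighv14-2: 0.05
d_weights:
  Ighd1-1: 0.40
  Ighd2-3: 0.35
  Ighd4-1: 0.15
  D-less: 0.10
j_weights:
  Ighj1: 0.25
  Ighj2: 0.25
  Ighj3: 0.25
  Ighj4: 0.25
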