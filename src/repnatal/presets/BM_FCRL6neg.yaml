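# Adult bone marrow FCRL6- pro B cells: Tdt on, moderate trimming,
# balanced V usage, higher Y101.
subset_label: BM_FCRL6neg
n_clones: 4000
clone_size: {distribution: geometric, mean: 3.0}
tdt_on: true
n_insert_mean: 4.0
trim_mean_v3: 0.3
trim_mean_d5: 1.0
trim_mean_d3: 1.0
trim_mean_j5: 1.0
y101_target: 0.36
max_rejections: 5000
v_weights:
  Ighv5-2: 0.16
  Ighv2-3: 0.14
  Ighv7-1: 0.13
  Ighv14-2: 0.10
  Ighv12-3: 0.11
  Ighv11-2: 0.11
  Ighv1-26: 0.13
  Ighv1-55: 0.12
d_weights:
  Ighd1-1: 0.40
  Ighd2-3: 0.38
  Ighd4-1: 0.19
  D-less: 0.03
j_weights:
  Ighj1: 0.25
  Ighj2: 0.25
  Ighj3: 0.25
  Ighj4: 0.25
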