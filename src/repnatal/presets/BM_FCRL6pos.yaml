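# Adult bone marrow FCRL6+ pro B cells: Tdt on (N-addition), heavier trimming
# than FCRL6-, distal V bias, reduced Y101.
subset_label: BM_FCRL6pos
n_clones: 4000
clone_size: {distribution: geometric, mean: 3.0}
tdt_on: true
n_insert_mean: 4.0
trim_mean_v3: 0.5
trim_mean_d5: 1.5
trim_mean_d3: 1.5
trim_mean_j5: 1.5
y101_target: 0.26
max_rejections: 5000
v_weights:
  Ighv1-26: 0.22
  Ighv1-55: 0.18
  Ighv11-2: 0.12
  Ighv12-3: 0.10
  Ighv5-2: 0.12
  Ighv2-3: 0.10
  Ighv7-1: 0.09
  Ighv14-2: 0.07
d_weights:
  Ighd1-1: 0.42
  Ighd2-3: 0.35
  Ighd4-1: 0.16
  D-less: 0.07
j_weights:
  Ighj1: 0.25
  Ighj2: 0.25
  Ighj3: 0.25
  Ighj4: 0.25
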