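populations:
- name: g1
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g2
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g3
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g4
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g5
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g6
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g7
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g8
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g9
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g10
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g11
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: g12
  N: 1000
  cls: graded
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.1
  nu: 250.0
  t_ref: 0.0
- name: s1
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s2
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s3
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s4
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s5
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s6
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s7
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s8
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s9
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s10
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s11
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
- name: s12
  N: 100
  cls: gating
  g_leak: 50.0
  V_leak: 0.0
  V_thres: 1.0
  tau: 0.005
  f: 0.028
  nu: 600.0
  t_ref: 0.004
blocks:
- source: g1
  target: g2
  S: 0.4
  p: 0.2
  K: 1.0
- source: g2
  target: g3
  S: 0.4
  p: 0.2
  K: 1.0
- source: g3
  target: g4
  S: 0.4
  p: 0.2
  K: 1.0
- source: g4
  target: g5
  S: 0.4
  p: 0.2
  K: 1.0
- source: g5
  target: g6
  S: 0.4
  p: 0.2
  K: 1.0
- source: g6
  target: g7
  S: 0.4
  p: 0.2
  K: 1.0
- source: g7
  target: g8
  S: 0.4
  p: 0.2
  K: 1.0
- source: g8
  target: g9
  S: 0.4
  p: 0.2
  K: 1.0
- source: g9
  target: g10
  S: 0.4
  p: 0.2
  K: 1.0
- source: g10
  target: g11
  S: 0.4
  p: 0.2
  K: 1.0
- source: g11
  target: g12
  S: 0.4
  p: 0.2
  K: 1.0
- source: s1
  target: s2
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s2
  target: s3
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s3
  target: s4
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s4
  target: s5
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s5
  target: s6
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s6
  target: s7
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s7
  target: s8
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s8
  target: s9
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s9
  target: s10
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s10
  target: s11
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s11
  target: s12
  S: 1.735294921875
  p: 0.5
  K: 1.0
- source: s1
  target: g1
  S: 0.8
  p: 0.05
  K: 1.0
- source: s2
  target: g2
  S: 0.8
  p: 0.05
  K: 1.0
- source: s3
  target: g3
  S: 0.8
  p: 0.05
  K: 1.0
- source: s4
  target: g4
  S: 0.8
  p: 0.05
  K: 1.0
- source: s5
  target: g5
  S: 0.8
  p: 0.05
  K: 1.0
- source: s6
  target: g6
  S: 0.8
  p: 0.05
  K: 1.0
- source: s7
  target: g7
  S: 0.8
  p: 0.05
  K: 1.0
- source: s8
  target: g8
  S: 0.8
  p: 0.05
  K: 1.0
- source: s9
  target: g9
  S: 0.8
  p: 0.05
  K: 1.0
- source: s10
  target: g10
  S: 0.8
  p: 0.05
  K: 1.0
- source: s11
  target: g11
  S: 0.8
  p: 0.05
  K: 1.0
- source: s12
  target: g12
  S: 0.8
  p: 0.05
  K: 1.0
groups:
  graded:
  - g1
  - g2
  - g3
  - g4
  - g5
  - g6
  - g7
  - g8
  - g9
  - g10
  - g11
  - g12
  gating:
  - s1
  - s2
  - s3
  - s4
  - s5
  - s6
  - s7
  - s8
  - s9
  - s10
  - s11
  - s12
stimuli:
- pop: s1
  t_on: 0.0
  t_off: 0.003
  amplitude: 600.0
sinusoids: []
seed: 0
meta:
  S11: 0.4
  p11: 0.2
  S22: 1.735294921875
  p22: 0.5
  f2: 0.028
  nu2: 600.0
  cyclic: false
  S12: 0.8
  p12: 0.05
  T0: 0.003366666666666667
  t_first: 0.0033833333333333337
  gate_len: 0.010100000000000001
  volley_width: 0.002423500000000001
  spikes_per_neuron: 0.9950000000000001
  probe_amplitudes:
  - 45.0
  - 52.0
  - 60.0
  name: fig1_sgsc
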