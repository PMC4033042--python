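# Izhikevich parameter sets for the four firing modes used in the
# thalamo-cortico-thalamic (TCT) network, one record per mode.
#
#   a        recovery time scale (1/ms in the model's normalized units)
#   b        recovery sensitivity to subthreshold v
#   c        post-spike reset potential (mV)
#   d        post-spike recovery increment
#   v_init   initial membrane potential (mV)
#   u_init   initial recovery-variable value
#   tau_syn_E / tau_syn_I   synaptic current decay constants (ms)
#   i_step   step-current amplitude used by the characterization protocol
#   cells    TCT populations that use this mode
#
# Note on v_init/u_init: the source table prints the initialization pair in
# the column order (u, v) = (-60..-70, 0); the magnitudes identify the first
# value as a membrane potential and the second as the recovery variable, so
# it is read here as v_init = -60/-70 mV and u_init = 0 (see docs/methods.md).
RS:
  name: regular spiking
  a: 0.02
  b: 0.2
  c: -65.0
  d: 6.0
  v_init: -60.0
  u_init: 0.0
  tau_syn_E: 5.0
  tau_syn_I: 6.0
  i_step: 9.0
  cells: [PY, SS, TCR]
FS:
  name: fast spiking
  a: 0.1
  b: 0.2
  c: -65.0
  d: 6.0
  v_init: -70.0
  u_init: 0.0
  tau_syn_E: 5.0
  tau_syn_I: 6.0
  i_step: 9.0
  cells: [B, IN]
LTS:
  name: low threshold spiking
  a: 0.01
  b: 0.2
  c: -65.0
  d: 6.0
  v_init: -70.0
  u_init: 0.0
  tau_syn_E: 5.0
  tau_syn_I: 6.0
  i_step: 25.0
  cells: [NB]
TB:
  name: tonic bursting
  a: 0.02
  b: 0.25
  c: -50.0
  d: 2.0
  v_init: -70.0
  u_init: 0.0
  tau_syn_E: 5.0
  tau_syn_I: 6.0
  i_step: 10.0
  cells: [TRN]
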