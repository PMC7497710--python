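# 2-state diffusion/active-transport particle (mRNA-style dynamics).
# Illustrative defaults, non-authoritative.
model: two_state
params:
  beta1: 0.5     # rate out of the transport state, 1/s
  beta2: 1.0     # rate out of the diffusing state, 1/s
  v: 1.0         # transport speed, µm/s
  D: 1.0         # free diffusivity, µm²/s
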