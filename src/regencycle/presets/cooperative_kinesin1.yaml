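# Cooperative one-directional transport by a team of kinesin-1 motors.
# Literature-style default kinetics, non-authoritative except the stall force
# F_s = 6 pN and detachment force scale F_d = 3 pN.
model: cooperative
params:
  N: 2
  v: 1.0        # load-free velocity, µm/s
  eps: 1.0      # load-free unbinding rate, 1/s
  pi: 5.0       # binding rate per unbound motor, 1/s
  F: 0.0        # external load, pN
  F_s: 6.0      # stall force, pN
  F_d: 3.0      # detachment force scale, pN
  w: 1.0        # force-velocity exponent (1 = linear)
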