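# Microtubule-pair sliding by a team of K bidirectional kinesin motors.
# Literature-style defaults, non-authoritative.
model: sliding
params:
  K: 35          # motors in the overlap region
  kappa0: 0.25   # force-free direction-switch rate, 1/s
  gamma: 1.0     # dimensionless load sensitivity (2 F_s / F_d)
  V_m: 0.78      # single-motor speed, µm/s
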