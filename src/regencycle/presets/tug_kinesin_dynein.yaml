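# Tug-of-war between kinesin-1 and conventional dynein teams.
# Literature-style default kinetics, non-authoritative except kinesin's
# F_s = 6 pN and F_d = 3 pN.
model: tug_of_war
params:
  plus:          # kinesin-1
    N: 2
    F_s: 6.0
    F_d: 3.0
    eps0: 1.0
    pi0: 5.0
    v_f: 1.0
    v_b: 0.006
  minus:         # conventional dynein
    N: 2
    F_s: 1.1
    F_d: 0.75
    eps0: 0.27
    pi0: 1.6
    v_f: 0.65
    v_b: 0.072
  rho: 1.0       # reattachment factor (1 = standard kinetics)
  D_c: 0.0       # unbound cargo diffusivity (0 = paused when detached)
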