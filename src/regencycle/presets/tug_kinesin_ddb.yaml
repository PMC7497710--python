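# Tug-of-war between kinesin-1 and dynein-dynactin-BicD2 (DDB) complexes.
# Literature-style default kinetics, non-authoritative except kinesin's
# F_s = 6 pN and F_d = 3 pN. DDB is far more competitive with kinesin than
# conventional dynein (higher stall and detachment forces, lower unbinding).
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
  minus:         # DDB complex
    N: 2
    F_s: 3.8
    F_d: 1.9
    eps0: 0.11
    pi0: 1.6
    v_f: 0.85
    v_b: 0.04
  rho: 1.0
  D_c: 0.0
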