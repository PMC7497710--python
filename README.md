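# regencycle

Renewal-reward analysis of semi-Markov switching transport.

Intracellular cargo — vesicles, mRNA granules, organelles — moves by
switching among qualitatively different behaviours: processive runs driven by
molecular motors, free diffusion, pauses. Two numbers summarize the long-time
transport that emerges from this switching: the **effective velocity**
`v_eff = lim X(t)/t` and the **effective diffusivity**
`D_eff = lim Var(X(t))/(2t)`. The velocity is easy (a stationary-occupancy
average of state velocities), but the diffusivity depends on the switching
*dynamics*, not just the occupancies, and is usually obtained from costly
stochastic simulation.

`regencycle` computes both — plus the expected cargo **run length** —
exactly, for any model in which the sequence of states forms a recurrent
Markov chain (sojourn times need *not* be exponential). The idea: the process
regenerates each time it enters a chosen base state. Let `ΔT` and `ΔX` be the
duration and displacement of one regeneration cycle. Renewal reward theory
and a functional CLT give

```
v_eff = E(ΔX) / E(ΔT)
D_eff = [ Var(ΔX) + v_eff² Var(ΔT) − 2 v_eff Cov(ΔX, ΔT) ] / (2 E(ΔT))
```

and the cycle moments follow from linear recursions on the substochastic
matrix `P̃` of transitions among non-base states, e.g.

```
E(R)   = (I − P̃)⁻¹ E(ρ̃)
E(R²)  = (I − P̃)⁻¹ [ E(ρ̃°²) + 2 diag(E(ρ̃)) P̃ E(R) ]
```

for any per-sojourn reward `ρ` (time, displacement, or their product), so a
model with dozens of states is analyzed with a handful of linear solves.
For the CTMC subclass an independent PDE-homogenization formula
(`v_eff = v·π`, `D_eff = d·π − v·(Āᵀ)⁻¹(v∘π − v_eff π)`) is included as a
cross-check, and Monte-Carlo simulators validate everything else.

Shipped model builders cover the standard motor-transport case studies:
2-state diffusion/advection and 4-state advection–reaction–diffusion
particles, cooperative transport by motor teams with a nonlinear
force–velocity relation, kinesin–dynein tug-of-war (with an optional enhanced
reattachment factor), and bidirectional microtubule sliding.

## Worked example

A particle alternates between free diffusion (`D = 0.7 µm²/s`, mean duration
`1/β₂ = 1/1.3 s`) and active transport (`v = 0.9 µm/s`, mean duration
`1/β₁ = 2 s`):

```python
from regencycle import (analyze, build_two_state,
                        simulate_endpoints, estimate_from_endpoints)

model = build_two_state(beta1=0.5, beta2=1.3, v=0.9, D=0.7)
et = analyze(model)
print(f"v_eff       = {et.v_eff:.6f} um/s")
print(f"D_eff       = {et.D_eff:.6f} um^2/s")
print(f"run length  = {et.run_length:.6f} um")

x = simulate_endpoints(model, 500, 5e4, seed=0)
est = estimate_from_endpoints(x, 5e4)
print(f"v_hat = {est.v_hat:.4f} +/- {est.se_v:.4f}")
```

prints

```
v_eff       = 0.650000 um/s
D_eff       = 0.284722 um^2/s
run length  = 1.800000 um
v_hat = 0.6501 +/- 0.0002
```

`v_eff = v β₂/(β₁+β₂) = 0.65`: the transport speed times the fraction of time
spent moving. `D_eff = D β₁/(β₁+β₂) + v² β₁β₂/(β₁+β₂)³ ≈ 0.285`: the
occupancy-weighted free diffusion plus the dispersion generated by switching
itself. The run length `E(ΔX) = v/β₁ = 1.8 µm` is the mean displacement per
cycle. The Monte-Carlo estimate over 500 realizations agrees with the
analytic value within its standard error.

The same pipeline runs from the shell:

```sh
regencycle presets                      # packaged parameter sets
regencycle analyze  --config src/regencycle/presets/two_state_mrna.yaml
regencycle simulate --config src/regencycle/presets/two_state_mrna.yaml --seed 1
regencycle sweep    --config src/regencycle/presets/cooperative_kinesin1.yaml \
                    --param F --values 0,2,4,6,8,10 --bound-velocity
```

Motor presets are literature-style defaults for kinesin-1, conventional
dynein and the DDB complex; they are illustrative, not authoritative fits.

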