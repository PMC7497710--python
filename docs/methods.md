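# Methods

## Model class

`regencycle` analyzes one-dimensional particle transport with switching
dynamics. The state process visits a finite set `S = {0, …, N}`; the sequence
of visited states `J_k` is a time-homogeneous recurrent Markov chain with
transition matrix `P` (zero diagonal — a "switch" always changes state).
Conditional on `J_k = j`, the sojourn time `τ` and the displacement `ξ`
accrued during that sojourn are drawn from a state-specific joint law,
independently of everything else. Sojourns need not be exponential, and `τ`
and `ξ` may be dependent (they are, for drift states, where `ξ = vτ`), so the
process is semi-Markov rather than a CTMC. Units are a convention: seconds,
micrometres, piconewtons.

Each `StateLaw` reduces to a five-moment bundle
`(Eτ, Eτ², Eξ, Eξ², Eτξ)` — all that the analytic pipeline consumes — plus an
exact sampler for the Monte-Carlo validators. Parametric families:

| family | sojourn | displacement | cov(τ, ξ) |
|---|---|---|---|
| `exp_drift(r, v)` | Exp(r) | `vτ` | `v/r²` |
| `exp_diffusion(r, D)` | Exp(r) | `√(2Dτ) Z` | 0 |
| `exp_pause(r)` | Exp(r) | 0 | 0 |
| `gamma_drift(k, r, v)` | Gamma(k, r) | `vτ` | `vk/r²` |
| `exp_drift_diffusion(r, v, D)` | Exp(r) | `vτ + √(2Dτ) Z` | `v/r²` |
| `general(…)` | raw moments | raw moments | `Eτξ − EτEξ` |

The combined drift+diffusion family exists because CTMC embedding of a state
with both `v ≠ 0` and `d ≠ 0` needs it; its bundle follows from `ξ = vτ +
√(2dτ)Z` with `Z ⟂ τ`: `Eξ² = v²Eτ² + 2d Eτ` and `Eτξ = v Eτ²`. Construction
validates `Eτ > 0`, `Eτ² ≥ (Eτ)²`, `Eξ² ≥ (Eξ)²` and Cauchy–Schwarz on the
central cross moment.

A CTMC specification (generator `A`, velocities `v`, diffusivities `d`) is
embedded via `P_ij = A_ij/λ_i`, `λ_i = Σ_{j≠i} A_ij`, with Exp(λ_i) sojourns;
absorbing states are rejected. The stationary distribution solves the
constrained linear system `[Aᵀ; 1ᵀ] π = [0; 1]` by least squares (the system
is consistent for irreducible `A`), never by eigen-iteration.

## Cycle decomposition and transport formulas

Visits to a designated base state regenerate the process. The cycle duration
`ΔT` and displacement `ΔX` split into the base sojourn `(τ₁, ξ₁)` and the
excursion totals `(ΔT̃, ΔX̃)` accumulated among non-base states. With `P̃`
the restriction of `P` to non-base states and `ρ` a per-sojourn reward, the
vector of excursion reward moments conditioned on the first non-base state
satisfies

    E(R)  = (I − P̃)⁻¹ E(ρ̃)
    E(Rⁿ) = (I − P̃)⁻¹ [ E(ρ̃°ⁿ) + Σ_{m=1}^{n−1} C(n,m) diag(E(ρ̃°⁽ⁿ⁻ᵐ⁾)) P̃ E(Rᵐ) ]

(implemented for general `n`, exercised up to `n = 2`), together with the
cross-moment recursion

    E(ΔT̃ΔX̃) = (I − P̃)⁻¹ [ E(τ̃∘ξ̃) + diag(E ξ̃) P̃ E(ΔT̃) + diag(E τ̃) P̃ E(ΔX̃) ].

The full-cycle statistics then combine the base law with the excursion
vectors through the first-step probabilities `p⁽¹⁾` (base row of `P`):

    E(ΔT)      = Eτ(0) + p⁽¹⁾·E(ΔT̃)
    Var(ΔT)    = Var τ(0) + p⁽¹⁾·E(ΔT̃²) − (p⁽¹⁾·E(ΔT̃))²
    Cov(ΔX,ΔT) = Cov(τ(0), ξ(0)) + p⁽¹⁾·E(ΔT̃ΔX̃) − (p⁽¹⁾·E(ΔT̃))(p⁽¹⁾·E(ΔX̃))

and analogously for `ΔX`. Effective transport:

    v_eff = E(ΔX)/E(ΔT),
    D_eff = [Var(ΔX) + v_eff² Var(ΔT) − 2 v_eff Cov(ΔX, ΔT)] / (2 E(ΔT)),

with `run_length = E(ΔX)` (meaningful when the base is complete detachment).
The bound-state velocity is `E(ΔX)/(E(ΔT) − Eτ(base))`: displacement per unit
attached time.

The excursion cross-moment vector is indexed by the *first non-base* state of
the cycle, which is the conditioning under which it is consumed by the
full-cycle covariance formula; this matches the polarization identity
`E(ΔT̃ΔX̃) = ¼[E((ΔX̃+ΔT̃)²) − E((ΔX̃−ΔT̃)²)]`, which the tests verify by
feeding the synthetic rewards `ξ ± τ` through the plain moment recursion.

The choice of base state is immaterial — the tests check `v_eff` and `D_eff`
agree to 1e-10 across all base choices — so builders pick whatever base is
natural (detachment for motor models, the stationary mode for the sliding
model). Degenerate one-state models are supported: the cycle is a single
base sojourn.

## Numerical choices

- All `(I − P̃)` systems reuse one LU factorization per model; explicit
  inverses are never formed. The homogenization correction solves a bordered
  KKT system `[[Aᵀ, 1], [1ᵀ, 0]]`, which pins the zero-sum solution branch
  exactly rather than relying on a pseudoinverse.
- Recurrence to base requires the spectral radius of `P̃` below `1 − 1e-9`;
  failure is an error (every recursion assumes it). States unreachable from
  the base are pruned with a logged warning — they never enter a cycle.
- Variances use the centred form `E(R²) − (ER)²`; values in `(−1e-12, 0)`
  are clipped to zero silently, anything more negative is clipped with a
  warning. `D_eff` gets the same floor.
- Validation tolerances: row sums of `P` within 1e-9 of 1; row sums of `A`
  within 1e-9 (scaled) of 0.

## Motor-model conventions

- **Cooperative team** (states `n = 0..N` motors attached): velocity
  `v_n = v(1 − (F/(nF_s))^w)`, unbinding `ε_n = nε e^{F/(nF_d)}`, binding
  `π_n = (N−n)π`. For `F > nF_s` the relation goes negative; by default the
  velocity is floored at zero (`clip_substall`) — a sub-stall team stalls
  rather than walks backwards — a documented modelling choice that makes wide
  load sweeps physically sensible.
- **Tug-of-war** (states `(n₊, n₋)`): shared-load cargo velocity
  `v_c = (n₊F_{s+} − n₋F_{s−}) / (n₊F_{s+}/v_{f+} + n₋F_{s−}/v_{b−})`, with
  the dragged speeds swapped when the minus team is at least as strong (ties
  use the stronger-minus branch). The inter-team cargo force uses the
  λ-interpolation of the two team stall forces and is defined as zero
  whenever either team is fully detached (the λ expression is singular
  there), so unbinding then occurs at the load-free rate. The reattachment
  rule is `N₊π₀₊` from full detachment and `(N₊−n₊)ρπ₀₊` otherwise (ρ = 1
  recovers standard kinetics). The unbound state is paused by default, or
  diffusive with `D_c > 0`. Plus-directed motion is positive; backward speeds
  are entered as magnitudes and negated internally.
- **Sliding** (states `i = 0..K` motors pushing positive): switch rates
  `κ_i⁺ = (K−i)κ₀e^{γi/K}`, `κ_i⁻ = iκ₀e^{γ(K−i)/K}`, velocity
  `V_m(2i−K)/K`.
- Packaged presets (kinesin-1, conventional dynein, DDB, sliding assay) are
  literature-style defaults meant for exploration, not authoritative
  parameter fits; the kinesin stall force 6 pN and detachment scale 3 pN are
  the only values treated as fixed reference points.

## Monte-Carlo validators

Trajectories start at the base state at `X = 0` — cycles are then iid from
the start, and path and cycle analyses share one convention. The final,
interrupted sojourn contributes its truncated displacement: pro rata
`v·elapsed` for drift laws, a fresh `√(2D·elapsed)Z` for diffusion (exact in
both cases by the Markov property of Brownian motion), pro-rata scaling of a
full draw for `general` laws (approximate); the residual estimator bias is
O(E(ΔT)/T_f). Endpoint-only simulation advances all realizations in lockstep
grouped by current state, so ensembles of 10³–10⁴ paths cost milliseconds;
full-path simulation records every epoch. Cycle sampling aborts past 10⁷
total steps (a nearly non-recurrent chain).

Estimators over `N_R` endpoints at horizon `T_f`:
`v̂ = mean(X_i)/T_f`, `D̂ = var(X_i)/(2T_f)` (unbiased sample variance).
Standard errors: variance of the mean for `v̂`; for `D̂`, the normal-theory
variance of a sample variance via the fourth central moment, with an optional
bootstrap over realizations for heavy-tailed cycles.

The SDE integrator realizes the tethered-cargo picture: in processive or
stalled states the cargo relaxes toward the theoretical motor position
`y₀ + v_j t'` with drift `−(κ/γ)(y − (v_j t' + y₀))` (spring constant κ,
drag γ), in the diffusive state the drift is zero; Euler–Maruyama with
stability guard `dt < 2γ/κ`. The tether parameters shipped in examples are
placeholders, not fits. Note the cargo systematically lags the motor by
`≈ γv_j/κ` per processive sojourn, so SDE-level long-run velocity matches the
embedded model only in the stiff-tether regime — the tests exercise exactly
that regime.

All randomness flows through one `numpy.random.Generator` passed explicitly
(an integer seed is accepted everywhere); fixed seeds reproduce event
sequences bit for bit.

## Problem sizes and what the tests show

The validation suite uses random models of 3–6 states with mixed law
families (including gamma sojourns), 2×10⁵ cycles for moment checks (4
standard-error bands), and 200-realization ensembles at horizons of ten
expected cycles for the finite-time convergence check (median relative error
≤ 10%, echoing the heuristic that ten regeneration cycles suffice for
10% accuracy). These sizes make the suite fast while leaving Monte-Carlo
bands far narrower than the effects being checked. Synthetic models drawn
this way probe the algebra of the pipeline, not the biology: passing tests
certify the recursions, embeddings and estimators, while quantitative claims
about a real cargo system depend on measured kinetic parameters that the
presets deliberately do not claim to be.

## Limitations

- Switching rates and transport coefficients are spatially homogeneous; no
  boundaries, no interacting particles.
- Only first and second cycle moments feed the transport formulas;
  large-deviation or distributional refinements are out of scope.
- The `general` law family participates in path simulation only when a
  sampler is attached, and its truncated-sojourn displacement is pro-rata
  (exact only for pure drift).
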