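"""Monte-Carlo validation of the renewal-reward predictions.

Trajectory-level simulation of switching models, first-return cycle sampling,
an Euler-Maruyama integrator for the tethered-cargo SDE picture, and the
empirical estimators of effective velocity and diffusivity

    v_hat = mean_i X_i(T_f) / T_f
    D_hat = sample_var_i X_i(T_f) / (2 T_f)

over ``N_R`` independent realizations run to a fixed horizon ``T_f``.

All randomness flows through a single ``numpy.random.Generator`` (or an
integer seed); fixed seeds reproduce runs bit for bit. Endpoint-only
simulation (`simulate_endpoints`, `sample_cycles`) is vectorized across
realizations by grouping paths on their current state, so large ensembles
stay cheap; `simulate_paths` records full event histories per path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .switching_model import SwitchingModel, ValidationError

__all__ = [
    "Trajectory",
    "EstimatedTransport",
    "simulate_paths",
    "simulate_endpoints",
    "estimate_transport",
    "estimate_from_endpoints",
    "sample_cycles",
    "simulate_sde_path",
]

_MAX_CYCLE_STEPS = 10**7


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Trajectory:
    """Piecewise record of one realization: positions at state-switch times."""

    times: np.ndarray        # s, increasing; switch times plus 0 and T_f
    positions: np.ndarray    # µm, aligned with times
    states: np.ndarray       # state index per epoch (len(times) - 1)
    epoch_times: np.ndarray  # s, the switch times t_k

    def __post_init__(self):
        if np.any(np.diff(self.times) < 0):
            raise ValidationError("trajectory times must be sorted")
        if len(self.positions) != len(self.times):
            raise ValidationError("positions and times must align")

    @property
    def final_position(self) -> float:
        return float(self.positions[-1])

    @property
    def horizon(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class EstimatedTransport:
    """Empirical transport estimates with standard errors."""

    v_hat: float
    D_hat: float
    se_v: float
    se_D: float
    N_R: int
    T_f: float


def _check_samplers(model: SwitchingModel) -> None:
    for i, law in enumerate(model.laws):
        if law.family == "general" and law.sampler is None:
            raise ValidationError(
                f"state {i} law has no sampler; use a parametric family or "
                "attach a sampler to simulate"
            )


def simulate_paths(model: SwitchingModel, N_R: int, T_f: float,
                   seed=None) -> list[Trajectory]:
    """Simulate ``N_R`` full trajectories of the switching process to ``T_f``.

    Paths start in the base state at X = 0. The final, interrupted sojourn
    contributes its truncated displacement (pro rata for drift, a fresh
    sqrt(2 D elapsed) Z draw for diffusion).
    """
    _check_samplers(model)
    if T_f <= 0:
        raise ValidationError("T_f must be positive")
    rng = _as_rng(seed)
    cum = np.cumsum(model.P, axis=1)
    out = []
    for _ in range(N_R):
        t, x, j = 0.0, 0.0, model.base_state
        times, pos, states = [0.0], [0.0], []
        while True:
            tau, xi = model.laws[j].sample(rng, 1)
            tau, xi = float(tau[0]), float(xi[0])
            if t + tau >= T_f:
                dx = float(model.laws[j].partial_displacement(
                    rng, np.array([T_f - t]))[0])
                states.append(j)
                times.append(T_f)
                pos.append(x + dx)
                break
            t += tau
            x += xi
            states.append(j)
            times.append(t)
            pos.append(x)
            j = int(np.searchsorted(cum[j], rng.random(), side="right"))
        out.append(Trajectory(
            times=np.array(times), positions=np.array(pos),
            states=np.array(states, dtype=int),
            epoch_times=np.array(times[1:-1]),
        ))
    return out


def simulate_endpoints(model: SwitchingModel, N_R: int, T_f: float,
                       seed=None) -> np.ndarray:
    """Final positions X_i(T_f) of ``N_R`` realizations (vectorized).

    Statistically identical to ``simulate_paths`` but only the endpoints are
    kept, with paths advanced in lockstep grouped by current state.
    """
    _check_samplers(model)
    if T_f <= 0:
        raise ValidationError("T_f must be positive")
    rng = _as_rng(seed)
    cum = np.cumsum(model.P, axis=1)
    t = np.zeros(N_R)
    x = np.zeros(N_R)
    state = np.full(N_R, model.base_state, dtype=int)
    active = np.ones(N_R, dtype=bool)
    while active.any():
        for j in np.unique(state[active]):
            idx = np.flatnonzero(active & (state == j))
            tau, xi = model.laws[j].sample(rng, idx.size)
            t_new = t[idx] + tau
            over = t_new >= T_f
            if over.any():
                fin = idx[over]
                x[fin] += model.laws[j].partial_displacement(rng, T_f - t[fin])
                t[fin] = T_f
                active[fin] = False
            cont = idx[~over]
            if cont.size:
                t[cont] = t_new[~over]
                x[cont] += xi[~over]
                u = rng.random(cont.size)
                state[cont] = np.searchsorted(cum[j], u, side="right")
    return x


def estimate_from_endpoints(x_final: np.ndarray, T_f: float) -> EstimatedTransport:
    """Transport estimators from final positions at a common horizon."""
    x = np.asarray(x_final, float)
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 realizations")
    mean = x.mean()
    s2 = x.var(ddof=1)
    v_hat = mean / T_f
    D_hat = s2 / (2.0 * T_f)
    se_v = np.sqrt(s2 / n) / T_f
    # normal-theory variance of the sample variance via the fourth central moment
    m4 = np.mean((x - mean) ** 4)
    var_s2 = (m4 - s2**2 * (n - 3) / (n - 1)) / n
    se_D = np.sqrt(max(var_s2, 0.0)) / (2.0 * T_f)
    return EstimatedTransport(v_hat=float(v_hat), D_hat=float(D_hat),
                              se_v=float(se_v), se_D=float(se_D),
                              N_R=n, T_f=float(T_f))


def estimate_transport(trajs: list[Trajectory],
                       bootstrap: int = 0, seed=None) -> EstimatedTransport:
    """Empirical effective velocity and diffusivity from trajectories.

    With ``bootstrap > 0`` the standard error of D_hat is replaced by a
    bootstrap over realizations (useful for heavy-tailed cycles).
    """
    if len(trajs) < 2:
        raise ValidationError("need at least 2 trajectories")
    T_f = trajs[0].horizon
    if any(abs(tr.horizon - T_f) > 1e-9 * max(T_f, 1.0) for tr in trajs):
        raise ValidationError("trajectories must share a common horizon")
    x = np.array([tr.final_position for tr in trajs])
    est = estimate_from_endpoints(x, T_f)
    if bootstrap > 0:
        rng = _as_rng(seed)
        n = x.size
        reps = np.empty(bootstrap)
        for b in range(bootstrap):
            reps[b] = x[rng.integers(0, n, n)].var(ddof=1) / (2.0 * T_f)
        est = EstimatedTransport(est.v_hat, est.D_hat, est.se_v,
                                 float(reps.std(ddof=1)), est.N_R, est.T_f)
    return est


def sample_cycles(model: SwitchingModel, n_cycles: int,
                  seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Sample (dT, dX) pairs over complete base-to-base regeneration cycles.

    Cycles are simulated directly from the base state (the process starts
    on-base, so no burn-in cycle needs discarding). Aborts if the ensemble
    exceeds a step budget, which would indicate a nearly non-recurrent chain.
    """
    _check_samplers(model)
    rng = _as_rng(seed)
    cum = np.cumsum(model.P, axis=1)
    base = model.base_state

    tau0, xi0 = model.laws[base].sample(rng, n_cycles)
    dT = tau0.copy()
    dX = xi0.copy()
    u = rng.random(n_cycles)
    state = np.searchsorted(cum[base], u, side="right")
    active = state != base
    if model.n_states == 1:
        return dT, dX
    steps = n_cycles
    while active.any():
        steps += int(active.sum())
        if steps > _MAX_CYCLE_STEPS:
            raise ValidationError("cycle sampling exceeded the step budget; "
                                  "chain is barely recurrent to base")
        for j in np.unique(state[active]):
            idx = np.flatnonzero(active & (state == j))
            tau, xi = model.laws[j].sample(rng, idx.size)
            dT[idx] += tau
            dX[idx] += xi
            u = rng.random(idx.size)
            nxt = np.searchsorted(cum[j], u, side="right")
            state[idx] = nxt
            active[idx[nxt == base]] = False
    return dT, dX


def simulate_sde_path(model: SwitchingModel, ou: dict, dt: float, T_f: float,
                      seed=None) -> Trajectory:
    """Euler-Maruyama path of the tethered-cargo SDE picture.

    In processive and stalled states the cargo position relaxes toward the
    theoretical motor position ``y0 + v_j t'`` through a linear tether:
    drift ``-(kappa / gamma) (y - (v_j t' + y0))`` with spring constant
    ``kappa`` (pN/µm) and drag ``gamma`` (pN s/µm); in the diffusive state
    the drift is zero. State sojourns are drawn from the model's laws; noise
    is ``sqrt(2 d_j) dW`` with ``d_j`` the diffusive state's D, or
    ``ou['d_bound']`` (default 0) while tethered.
    """
    _check_samplers(model)
    kappa, gamma = float(ou["kappa"]), float(ou["gamma"])
    d_bound = float(ou.get("d_bound", 0.0))
    if kappa <= 0 or gamma <= 0:
        raise ValidationError("kappa and gamma must be positive")
    if dt <= 0 or dt >= 2.0 * gamma / kappa:
        raise ValidationError("dt must satisfy 0 < dt < 2 gamma / kappa for "
                              "stable integration")
    rng = _as_rng(seed)
    cum = np.cumsum(model.P, axis=1)

    times, pos, states, epochs = [0.0], [0.0], [], []
    t, x, j = 0.0, 0.0, model.base_state
    while t < T_f:
        tau = float(model.laws[j].sample(rng, 1)[0][0])
        t_end = min(t + tau, T_f)
        law = model.laws[j]
        diffusive = law.family == "exp_diffusion"
        v_j = float(law.params.get("v", 0.0))
        d_j = float(law.params.get("D", 0.0)) if diffusive else d_bound
        y0, t0 = x, t
        n_steps = max(1, int(np.ceil((t_end - t) / dt)))
        h = (t_end - t) / n_steps
        noise = np.sqrt(2.0 * d_j * h) * rng.standard_normal(n_steps)
        for s in range(n_steps):
            drift = 0.0 if diffusive else (
                -(kappa / gamma) * (x - (v_j * (t - t0) + y0)))
            x = x + drift * h + noise[s]
            t = t + h
            times.append(t)
            pos.append(x)
        states.append(j)
        if t < T_f:
            epochs.append(t)
        j = int(np.searchsorted(cum[j], rng.random(), side="right"))
    return Trajectory(times=np.array(times), positions=np.array(pos),
                      states=np.array(states, dtype=int),
                      epoch_times=np.array(epochs))
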