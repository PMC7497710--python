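"""Builders translating biophysical motor-transport models into switching models.

Four families of case studies are covered:

- a 2-state diffusion/advection particle (e.g. mRNA transport),
- a 4-state diffusion/forward/backward/pause particle,
- cooperative transport by up to N identical motors pulling one way against a
  load force, with a nonlinear force-velocity relation,
- tug-of-war transport by opposing motor teams (with an optional enhanced
  reattachment factor), and a microtubule-sliding model driven by a fixed
  number of bidirectional motors.

Each builder returns a :class:`~regencycle.switching_model.SwitchingModel`
ready for the cycle-moment pipeline. Conventions: plus-directed motion is
positive; backward speeds are entered as positive numbers and negated
internally; units are s, µm, pN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .switching_model import (
    RateMatrix,
    SwitchingModel,
    ValidationError,
    embed_ctmc,
    make_state_law,
    stationary_distribution,
)

__all__ = [
    "CooperativeParams",
    "MotorParams",
    "TugOfWarParams",
    "SlidingParams",
    "build_two_state",
    "build_four_state",
    "build_cooperative",
    "build_tug_of_war",
    "build_sliding",
]


def build_two_state(beta1: float, beta2: float, v: float, D: float) -> SwitchingModel:
    """2-state particle: free diffusion (base) alternating with transport.

    The diffusing state has mean duration 1/beta2 and diffusivity D; the
    active state has mean duration 1/beta1 and speed v.
    """
    if min(beta1, beta2, v, D) <= 0:
        raise ValidationError("all 2-state parameters must be positive")
    P = np.array([[0.0, 1.0], [1.0, 0.0]])
    laws = [make_state_law("exp_diffusion", r=beta2, D=D),
            make_state_law("exp_drift", r=beta1, v=v)]
    return SwitchingModel(P, laws, base_state=0,
                          labels=["diffusing", "transport"])


def build_four_state(rates, v_plus: float, v_minus: float, D: float,
                     base_state: int = 0) -> SwitchingModel:
    """4-state particle: diffusing, forward, backward and paused states.

    ``rates`` is a 4x4 array of transition rates (diagonal ignored) between
    states ordered (diffusing, forward, backward, paused). ``v_minus`` is a
    positive backward speed, negated internally.
    """
    rates = np.asarray(rates, float)
    if rates.shape != (4, 4):
        raise ValidationError("rates must be 4x4")
    if v_plus <= 0 or v_minus <= 0 or D <= 0:
        raise ValidationError("speeds and diffusivity must be positive")
    rm = RateMatrix.from_rates(rates,
                               v=[0.0, v_plus, -v_minus, 0.0],
                               d=[D, 0.0, 0.0, 0.0])
    model = embed_ctmc(rm, base_state=base_state)
    model.labels = ["diffusing", "forward", "backward", "paused"]
    return model


# ---------------------------------------------------------------------------
# cooperative transport (one team of identical motors against a load)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CooperativeParams:
    """Parameters of cooperative transport by up to N identical motors.

    v : load-free motor velocity (µm/s); eps : load-free unbinding rate (1/s);
    pi : binding rate per unbound motor (1/s); F : external load force (pN);
    F_s : stall force (pN); F_d : detachment force scale (pN); w : exponent of
    the force-velocity relation (1 linear, <1 sub-linear, >1 super-linear);
    clip_substall : floor per-state velocities at 0 beyond stall instead of
    letting the force-velocity relation go negative.
    """

    N: int
    v: float
    eps: float
    pi: float
    F: float = 0.0
    F_s: float = 6.0
    F_d: float = 3.0
    w: float = 1.0
    clip_substall: bool = True

    def __post_init__(self):
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if min(self.v, self.eps, self.pi, self.F_s, self.F_d, self.w) <= 0:
            raise ValidationError("v, eps, pi, F_s, F_d, w must be positive")
        if self.F < 0:
            raise ValidationError("load force must be >= 0")

    def velocity(self, n: int) -> float:
        """Cargo velocity with n motors engaged: v (1 - (F/(n F_s))^w)."""
        if n == 0:
            return 0.0
        vn = self.v * (1.0 - (self.F / (n * self.F_s)) ** self.w)
        if self.clip_substall:
            vn = max(vn, 0.0)
        return vn

    def unbind_rate(self, n: int) -> float:
        """eps_n = n eps exp(F / (n F_d))."""
        if n == 0:
            return 0.0
        return n * self.eps * np.exp(self.F / (n * self.F_d))

    def bind_rate(self, n: int) -> float:
        """pi_n = (N - n) pi."""
        return (self.N - n) * self.pi


def build_cooperative(p: CooperativeParams) -> SwitchingModel:
    """Birth-death chain on the number of engaged motors n = 0..N.

    State n moves at the load-dependent velocity ``p.velocity(n)`` for an
    exponential time with rate eps_n + pi_n; the base state is complete
    detachment (n = 0), so the cycle displacement is the cargo run length.
    """
    N = p.N
    n_states = N + 1
    P = np.zeros((n_states, n_states))
    laws = []
    for n in range(n_states):
        eps_n, pi_n = p.unbind_rate(n), p.bind_rate(n)
        r_out = eps_n + pi_n
        if n > 0:
            P[n, n - 1] = eps_n / r_out
        if n < N:
            P[n, n + 1] = pi_n / r_out
        vn = p.velocity(n)
        if vn == 0.0:
            laws.append(make_state_law("exp_pause", r=r_out))
        else:
            laws.append(make_state_law("exp_drift", r=r_out, v=vn))
    return SwitchingModel(P, laws, base_state=0,
                          labels=[f"{n} bound" for n in range(n_states)])


# ---------------------------------------------------------------------------
# tug-of-war transport (opposing teams)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotorParams:
    """Single-species motor kinetics for the tug-of-war model.

    N : team size; F_s : stall force (pN); F_d : detachment force scale (pN);
    eps0 : load-free unbinding rate (1/s); pi0 : binding rate (1/s);
    v_f : forward speed in the motor's preferred direction (µm/s);
    v_b : slow backward speed when dragged (µm/s). Speeds are magnitudes.
    """

    N: int
    F_s: float
    F_d: float
    eps0: float
    pi0: float
    v_f: float
    v_b: float

    def __post_init__(self):
        if self.N < 0:
            raise ValidationError("team size must be >= 0")
        if self.N > 0 and min(self.F_s, self.F_d, self.eps0, self.pi0,
                              self.v_f, self.v_b) <= 0:
            raise ValidationError("motor rates, forces and speeds must be positive")


@dataclass(frozen=True)
class TugOfWarParams:
    """Two opposing motor teams plus reattachment and unbound-cargo options.

    rho >= 1 amplifies rebinding while at least one motor is attached
    (rho = 1 recovers the standard kinetics); D_c > 0 makes the fully
    detached cargo slowly diffusive instead of paused.
    """

    plus: MotorParams
    minus: MotorParams
    rho: float = 1.0
    D_c: float = 0.0

    def __post_init__(self):
        if self.plus.N == 0 and self.minus.N == 0:
            raise ValidationError("at least one team must be non-empty")
        if self.rho < 1:
            raise ValidationError("reattachment factor rho must be >= 1")
        if self.D_c < 0:
            raise ValidationError("unbound diffusivity must be >= 0")


def _cargo_velocity(n_p: int, n_m: int, p: TugOfWarParams) -> float:
    """Shared-load cargo velocity with n_p plus and n_m minus motors engaged."""
    if n_p == 0 and n_m == 0:
        return 0.0
    fp = n_p * p.plus.F_s
    fm = n_m * p.minus.F_s
    if fp > fm:      # stronger plus team
        denom = fp / p.plus.v_f + (fm / p.minus.v_b if fm > 0 else 0.0)
    else:            # stronger minus team (ties included): dragged speeds swap
        denom = (fp / p.plus.v_b if fp > 0 else 0.0) + fm / p.minus.v_f
    return (fp - fm) / denom


def _cargo_force(n_p: int, n_m: int, p: TugOfWarParams) -> float:
    """Inter-team load on each side; zero when either team is detached."""
    if n_p == 0 or n_m == 0:
        return 0.0
    fp = n_p * p.plus.F_s
    fm = n_m * p.minus.F_s
    if fp > fm:
        lam = 1.0 / (1.0 + fp * p.minus.v_b / (fm * p.plus.v_f))
        return lam * fp + (1.0 - lam) * fm
    lam = 1.0 / (1.0 + fm * p.plus.v_b / (fp * p.minus.v_f))
    return lam * fm + (1.0 - lam) * fp


def build_tug_of_war(p: TugOfWarParams) -> SwitchingModel:
    """Tug-of-war switching model on states (n_plus, n_minus).

    Unbinding rates grow exponentially in the inter-team cargo force with the
    detachment force scale; binding follows the reattachment rule:
    ``N pi0`` from full detachment, ``(N - n) rho pi0`` otherwise. The base
    state is full detachment (paused, or diffusive when ``D_c > 0``), so the
    cycle displacement is the cargo run length.
    """
    Np, Nm = p.plus.N, p.minus.N
    n_states = (Np + 1) * (Nm + 1)

    def idx(n_p, n_m):
        return n_p * (Nm + 1) + n_m

    R = np.zeros((n_states, n_states))
    v = np.zeros(n_states)
    d = np.zeros(n_states)
    labels = []
    for n_p in range(Np + 1):
        for n_m in range(Nm + 1):
            i = idx(n_p, n_m)
            labels.append(f"(+{n_p},-{n_m})")
            F_c = _cargo_force(n_p, n_m, p)
            attached = (n_p + n_m) > 0
            # unbinding
            if n_p > 0:
                R[i, idx(n_p - 1, n_m)] = (
                    n_p * p.plus.eps0 * np.exp(F_c / (n_p * p.plus.F_d)))
            if n_m > 0:
                R[i, idx(n_p, n_m - 1)] = (
                    n_m * p.minus.eps0 * np.exp(F_c / (n_m * p.minus.F_d)))
            # binding, with reattachment enhancement when already attached
            if n_p < Np:
                rate = (Np - n_p) * p.plus.pi0 * (p.rho if attached else 1.0)
                if n_p + n_m == 0:
                    rate = Np * p.plus.pi0
                R[i, idx(n_p + 1, n_m)] = rate
            if n_m < Nm:
                rate = (Nm - n_m) * p.minus.pi0 * (p.rho if attached else 1.0)
                if n_p + n_m == 0:
                    rate = Nm * p.minus.pi0
                R[i, idx(n_p, n_m + 1)] = rate
            v[i] = _cargo_velocity(n_p, n_m, p)
            if not attached:
                d[i] = p.D_c
    rm = RateMatrix.from_rates(R, v, d)
    model = embed_ctmc(rm, base_state=idx(0, 0))
    model.labels = labels
    return model


# ---------------------------------------------------------------------------
# microtubule sliding by bidirectional motor teams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlidingParams:
    """Microtubule-pair sliding driven by K motors split between directions.

    K : total number of motors in the overlap region; kappa0 : force-free
    direction-switch rate (1/s); gamma : dimensionless load sensitivity
    (twice the stall force over the detachment force scale); V_m :
    single-motor speed (µm/s).
    """

    K: int
    kappa0: float
    gamma: float
    V_m: float

    def __post_init__(self):
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if self.kappa0 <= 0 or self.V_m <= 0:
            raise ValidationError("kappa0 and V_m must be positive")
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")


def build_sliding(p: SlidingParams) -> SwitchingModel:
    """Birth-death chain on i = number of motors pushing in the + direction.

    Switch rates ``kappa_i+ = (K - i) kappa0 exp(gamma i / K)`` and
    ``kappa_i- = i kappa0 exp(gamma (K - i) / K)``; relative sliding velocity
    ``V_m (2 i - K) / K``. The base state is the most occupied state under
    the stationary distribution (the result is base-invariant).
    """
    K = p.K
    n_states = K + 1
    R = np.zeros((n_states, n_states))
    v = np.zeros(n_states)
    for i in range(n_states):
        if i < K:
            R[i, i + 1] = (K - i) * p.kappa0 * np.exp(p.gamma * i / K)
        if i > 0:
            R[i, i - 1] = i * p.kappa0 * np.exp(p.gamma * (K - i) / K)
        v[i] = p.V_m * (2 * i - K) / K
    rm = RateMatrix.from_rates(R, v, np.zeros(n_states))
    base = int(np.argmax(stationary_distribution(rm)))
    model = embed_ctmc(rm, base_state=base)
    model.labels = [f"{i}+/{K - i}-" for i in range(n_states)]
    return model
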