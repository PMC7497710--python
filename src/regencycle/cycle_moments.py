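"""First-return cycle moments and effective transport coefficients.

The long-run behaviour of a recurrent switching process is governed by the
statistics of one regeneration cycle: the time ``dT`` and displacement ``dX``
accumulated between successive visits to the base state. Their first and
second moments follow from linear recursions on the substochastic matrix
``P_tilde`` of transitions among non-base states: with the fundamental matrix
``(I - P_tilde)^{-1}``, the n-th moment of a reward accumulated before
returning to base satisfies

    E(R)   = (I - P)~^{-1} E(rho)
    E(R^n) = (I - P)~^{-1} [ E(rho^n)
               + sum_{m<n} C(n, m) diag(E(rho^{n-m})) P~ E(R^m) ]

componentwise over the starting state, together with an analogous cross-moment
recursion for E(dT~ dX~). Renewal reward theory then gives

    v_eff = E(dX) / E(dT)
    D_eff = [Var(dX) + v_eff^2 Var(dT) - 2 v_eff Cov(dX, dT)] / (2 E(dT))

and the expected run length E(dX) when the base state is complete detachment.

All (I - P~) systems share one LU factorization; explicit inverses are never
formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .switching_model import SwitchingModel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CycleStats",
    "EffectiveTransport",
    "reward_moment",
    "cross_moment",
    "cycle_statistics",
    "effective_transport",
    "bound_state_velocity",
    "analyze",
]

_VAR_FLOOR = -1e-12


@dataclass(frozen=True)
class CycleStats:
    """Moments of the regeneration-cycle duration dT (s) and reward dX (µm).

    The ``*_excl`` vectors are conditioned on the first non-base state of the
    cycle and exclude the base sojourn (the tilde quantities); scalar fields
    are full-cycle statistics including the base sojourn.
    """

    E_dT: float
    E_dX: float
    Var_dT: float
    Var_dX: float
    Cov_dXdT: float
    E_dT_excl: np.ndarray
    E_dX_excl: np.ndarray
    E_dT2_excl: np.ndarray
    E_dX2_excl: np.ndarray
    E_dTdX_excl: np.ndarray

    def validate(self) -> None:
        if not self.E_dT > 0:
            raise ValidationError("mean cycle duration must be positive")
        if self.Var_dT < 0 or self.Var_dX < 0:
            raise ValidationError("negative cycle variance")
        if self.Cov_dXdT**2 > self.Var_dT * self.Var_dX * (1 + 1e-9) + 1e-12:
            raise ValidationError("cycle covariance violates Cauchy-Schwarz")


@dataclass(frozen=True)
class EffectiveTransport:
    """Long-run transport coefficients derived from cycle statistics."""

    v_eff: float          # µm/s
    D_eff: float          # µm²/s
    run_length: float     # µm, = E(dX)
    cycle_stats: CycleStats | None = None


def _lu_of(P_tilde: np.ndarray):
    P_tilde = np.asarray(P_tilde, float)
    n = P_tilde.shape[0]
    try:
        return lu_factor(np.eye(n) - P_tilde)
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise ValidationError("I - P_tilde is singular: chain not recurrent "
                              "to the base state") from e


def reward_moment(P_tilde, moment_vectors, n: int) -> np.ndarray:
    """n-th moment of the reward accumulated before first return to base.

    Parameters
    ----------
    P_tilde : substochastic matrix among non-base states.
    moment_vectors : sequence whose m-th entry (m = 1..n, index m-1) is the
        vector of per-state raw reward moments E(rho(i)^m).
    n : moment order.

    Returns the vector over starting states i of E(R^n | first state i),
    solving the recursion by LU-backed linear solves.
    """
    P_tilde = np.atleast_2d(np.asarray(P_tilde, float))
    if n < 1:
        raise ValueError("moment order must be >= 1")
    if len(moment_vectors) < n:
        raise ValueError(f"need moment vectors for orders 1..{n}")
    mv = [np.atleast_1d(np.asarray(m, float)) for m in moment_vectors[:n]]
    lu = _lu_of(P_tilde)
    E_R = [lu_solve(lu, mv[0])]
    for order in range(2, n + 1):
        rhs = mv[order - 1].copy()
        for m in range(1, order):
            rhs += comb(order, m) * mv[order - m - 1] * (P_tilde @ E_R[m - 1])
        E_R.append(lu_solve(lu, rhs))
    return E_R[n - 1]


def cross_moment(P_tilde, E_tauxi, E_tau, E_xi, E_dT_excl, E_dX_excl) -> np.ndarray:
    """Cross moment E(dT~ dX~ | first state i) over non-base starting states.

    Combines the per-state cross moments E(tau(i) xi(i)) with the first-moment
    vectors of the remaining cycle.
    """
    P_tilde = np.atleast_2d(np.asarray(P_tilde, float))
    E_tauxi = np.atleast_1d(np.asarray(E_tauxi, float))
    E_tau = np.atleast_1d(np.asarray(E_tau, float))
    E_xi = np.atleast_1d(np.asarray(E_xi, float))
    lu = _lu_of(P_tilde)
    rhs = (E_tauxi
           + E_xi * (P_tilde @ np.atleast_1d(E_dT_excl))
           + E_tau * (P_tilde @ np.atleast_1d(E_dX_excl)))
    return lu_solve(lu, rhs)


def _clip_var(x: float, what: str) -> float:
    if x < 0:
        if x < _VAR_FLOOR:
            logger.warning("negative %s (%.3g) clipped to 0", what, x)
        return 0.0
    return x


def cycle_statistics(model: SwitchingModel) -> CycleStats:
    """Full regeneration-cycle statistics of a switching model.

    Decomposes the cycle into the base sojourn and the excursion among
    non-base states, runs the moment and cross-moment recursions, and
    assembles mean, variance and covariance of (dT, dX).
    """
    base = model.laws[model.base_state]
    if model.n_states == 1:
        # degenerate cycle: a single base sojourn
        empty = np.zeros(0)
        cs = CycleStats(
            E_dT=base.E_tau, E_dX=base.E_xi,
            Var_dT=_clip_var(base.var_tau, "Var(dT)"),
            Var_dX=_clip_var(base.var_xi, "Var(dX)"),
            Cov_dXdT=base.cov_tau_xi,
            E_dT_excl=empty, E_dX_excl=empty, E_dT2_excl=empty,
            E_dX2_excl=empty, E_dTdX_excl=empty,
        )
        cs.validate()
        return cs

    nb = model.non_base
    Pt = model.P_tilde
    E_tau, E_tau2, E_xi, E_xi2, E_tauxi = model.law_moment_vectors()
    t1, t2 = E_tau[nb], E_tau2[nb]
    x1, x2 = E_xi[nb], E_xi2[nb]
    tx = E_tauxi[nb]

    lu = _lu_of(Pt)
    E_dT_excl = lu_solve(lu, t1)
    E_dX_excl = lu_solve(lu, x1)
    E_dT2_excl = lu_solve(lu, t2 + 2.0 * t1 * (Pt @ E_dT_excl))
    E_dX2_excl = lu_solve(lu, x2 + 2.0 * x1 * (Pt @ E_dX_excl))
    E_dTdX_excl = lu_solve(lu, tx + x1 * (Pt @ E_dT_excl) + t1 * (Pt @ E_dX_excl))

    p1 = model.p1
    mT, mX = p1 @ E_dT_excl, p1 @ E_dX_excl
    cs = CycleStats(
        E_dT=base.E_tau + mT,
        E_dX=base.E_xi + mX,
        Var_dT=_clip_var(base.var_tau + p1 @ E_dT2_excl - mT**2, "Var(dT)"),
        Var_dX=_clip_var(base.var_xi + p1 @ E_dX2_excl - mX**2, "Var(dX)"),
        Cov_dXdT=base.cov_tau_xi + p1 @ E_dTdX_excl - mT * mX,
        E_dT_excl=E_dT_excl, E_dX_excl=E_dX_excl,
        E_dT2_excl=E_dT2_excl, E_dX2_excl=E_dX2_excl,
        E_dTdX_excl=E_dTdX_excl,
    )
    cs.validate()
    return cs


def effective_transport(cs: CycleStats) -> EffectiveTransport:
    """Renewal-reward effective velocity, diffusivity and run length."""
    v_eff = cs.E_dX / cs.E_dT
    sigma2 = cs.Var_dX + v_eff**2 * cs.Var_dT - 2.0 * v_eff * cs.Cov_dXdT
    D_eff = sigma2 / (2.0 * cs.E_dT)
    if D_eff < 0:
        if D_eff < _VAR_FLOOR:
            logger.warning("negative D_eff (%.3g) clipped to 0", D_eff)
        D_eff = 0.0
    return EffectiveTransport(v_eff=float(v_eff), D_eff=float(D_eff),
                              run_length=float(cs.E_dX), cycle_stats=cs)


def analyze(model: SwitchingModel) -> EffectiveTransport:
    """Cycle statistics and effective transport in one call."""
    return effective_transport(cycle_statistics(model))


def bound_state_velocity(model: SwitchingModel) -> float:
    """Effective velocity averaged over the bound (non-base) states only.

    Assumes the base state is the fully detached state, visited exactly once
    per cycle; the bound-state velocity is the cycle displacement per unit
    time spent off the base state.
    """
    cs = cycle_statistics(model)
    bound_time = cs.E_dT - model.laws[model.base_state].E_tau
    if bound_time <= 0:
        raise ValidationError("cycle spends no time outside the base state")
    return float(cs.E_dX / bound_time)
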