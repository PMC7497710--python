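"""Semi-Markov switching process models.

A particle switches among a finite set of biophysical states (diffusing,
processive transport, paused, ...). The sequence of visited states forms a
discrete-time Markov chain with zero diagonal; within each sojourn the state
determines the joint law of the sojourn time ``tau`` (s) and the spatial
displacement ``xi`` (µm). Everything downstream (cycle moments, effective
transport) consumes only the first/second/cross moments of ``(tau, xi)`` per
state, the embedded transition matrix ``P`` and a designated base state whose
visits mark regeneration times.

Units are a convention throughout the package: seconds, micrometres and
piconewtons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "StateLaw",
    "SwitchingModel",
    "RateMatrix",
    "make_state_law",
    "embed_ctmc",
    "stationary_distribution",
]

#: families with closed-form moment bundles
_FAMILIES = (
    "exp_drift",
    "exp_diffusion",
    "exp_pause",
    "gamma_drift",
    "exp_drift_diffusion",
    "general",
)

_MOMENT_KEYS = ("E_tau", "E_tau2", "E_xi", "E_xi2", "E_tauxi")


class ValidationError(ValueError):
    """A model or law failed its structural invariants."""


@dataclass(frozen=True)
class StateLaw:
    """Joint law of (sojourn time, displacement) for one state.

    The five-moment bundle ``(E tau, E tau^2, E xi, E xi^2, E tau*xi)`` is all
    the analytic pipeline needs; parametric families additionally carry an
    exact sampler used by the Monte-Carlo validators.
    """

    family: str
    params: dict = field(default_factory=dict)
    E_tau: float = 0.0
    E_tau2: float = 0.0
    E_xi: float = 0.0
    E_xi2: float = 0.0
    E_tauxi: float = 0.0
    sampler: Callable | None = None

    # -- derived central moments -------------------------------------------
    @property
    def var_tau(self) -> float:
        return self.E_tau2 - self.E_tau**2

    @property
    def var_xi(self) -> float:
        return self.E_xi2 - self.E_xi**2

    @property
    def cov_tau_xi(self) -> float:
        return self.E_tauxi - self.E_tau * self.E_xi

    @property
    def moments(self) -> tuple[float, float, float, float, float]:
        return (self.E_tau, self.E_tau2, self.E_xi, self.E_xi2, self.E_tauxi)

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown law family {self.family!r}")
        if not self.E_tau > 0:
            raise ValidationError("E(tau) must be positive")
        slack = 1e-12 * max(1.0, abs(self.E_tau2), abs(self.E_xi2))
        if self.var_tau < -slack or self.var_xi < -slack:
            raise ValidationError("second moments below squared means")
        # Cauchy-Schwarz on central moments
        bound = math.sqrt(max(self.var_tau, 0.0) * max(self.var_xi, 0.0))
        if abs(self.cov_tau_xi) > bound + 1e-9 * max(1.0, bound):
            raise ValidationError("cov(tau, xi) violates Cauchy-Schwarz")

    # -- sampling ----------------------------------------------------------
    def sample(self, rng: np.random.Generator, size: int = 1):
        """Draw ``size`` iid pairs (tau, xi) as two arrays."""
        p = self.params
        if self.family == "exp_drift":
            tau = rng.exponential(1.0 / p["r"], size)
            return tau, p["v"] * tau
        if self.family == "exp_diffusion":
            tau = rng.exponential(1.0 / p["r"], size)
            return tau, np.sqrt(2.0 * p["D"] * tau) * rng.standard_normal(size)
        if self.family == "exp_pause":
            tau = rng.exponential(1.0 / p["r"], size)
            return tau, np.zeros(size)
        if self.family == "gamma_drift":
            tau = rng.gamma(p["k"], 1.0 / p["r"], size)
            return tau, p["v"] * tau
        if self.family == "exp_drift_diffusion":
            tau = rng.exponential(1.0 / p["r"], size)
            xi = p["v"] * tau + np.sqrt(2.0 * p["D"] * tau) * rng.standard_normal(size)
            return tau, xi
        if self.sampler is None:
            raise ValidationError(
                "law of family 'general' has no sampler; supply one or use a "
                "parametric family"
            )
        tau, xi = self.sampler(rng, size)
        return np.asarray(tau, float), np.asarray(xi, float)

    def partial_displacement(self, rng: np.random.Generator, elapsed):
        """Displacement accrued over a truncated sojourn of length ``elapsed``.

        Exact for the parametric families (drift accrues pro rata, diffusion
        by a fresh sqrt(2 D elapsed) Z draw); the general family scales a full
        draw pro rata, which is exact for pure-drift laws and approximate
        otherwise.
        """
        elapsed = np.asarray(elapsed, float)
        p = self.params
        if self.family in ("exp_drift", "gamma_drift"):
            return p["v"] * elapsed
        if self.family == "exp_pause":
            return np.zeros_like(elapsed)
        if self.family == "exp_diffusion":
            z = rng.standard_normal(elapsed.shape)
            return np.sqrt(2.0 * p["D"] * elapsed) * z
        if self.family == "exp_drift_diffusion":
            z = rng.standard_normal(elapsed.shape)
            return p["v"] * elapsed + np.sqrt(2.0 * p["D"] * elapsed) * z
        tau, xi = self.sample(rng, elapsed.size)
        return (xi * elapsed.ravel() / tau).reshape(elapsed.shape)


def make_state_law(family: str, **params) -> StateLaw:
    """Build a :class:`StateLaw` with its analytic moment bundle.

    Families and parameters (rates in 1/s, speeds in µm/s, D in µm²/s):

    - ``exp_drift(r, v)``:      tau ~ Exp(r), xi = v tau
    - ``exp_diffusion(r, D)``:  tau ~ Exp(r), xi = sqrt(2 D tau) Z
    - ``exp_pause(r)``:         tau ~ Exp(r), xi = 0
    - ``gamma_drift(k, r, v)``: tau ~ Gamma(shape k, rate r), xi = v tau
    - ``exp_drift_diffusion(r, v, D)``: tau ~ Exp(r), xi = v tau + sqrt(2 D tau) Z
    - ``general(E_tau, E_tau2, E_xi, E_xi2, E_tauxi[, sampler])``: raw moments
    """
    if family not in _FAMILIES:
        raise ValidationError(f"unknown law family {family!r}")

    if family == "general":
        missing = [k for k in _MOMENT_KEYS if k not in params]
        if missing:
            raise ValidationError(f"general law missing moments: {missing}")
        law = StateLaw(
            family="general",
            params={},
            sampler=params.get("sampler"),
            **{k: float(params[k]) for k in _MOMENT_KEYS},
        )
        law.validate()
        return law

    r = float(params["r"]) if "r" in params else None
    if r is None or r <= 0:
        raise ValidationError(f"{family} requires a positive rate r")
    if family == "exp_drift":
        v = float(params["v"])
        m = (1 / r, 2 / r**2, v / r, 2 * v**2 / r**2, 2 * v / r**2)
    elif family == "exp_diffusion":
        D = float(params["D"])
        if D < 0:
            raise ValidationError("diffusivity must be >= 0")
        m = (1 / r, 2 / r**2, 0.0, 2 * D / r, 0.0)
    elif family == "exp_pause":
        m = (1 / r, 2 / r**2, 0.0, 0.0, 0.0)
    elif family == "gamma_drift":
        k, v = float(params["k"]), float(params["v"])
        if k <= 0:
            raise ValidationError("gamma shape must be positive")
        m = (k / r, k * (k + 1) / r**2, v * k / r,
             v**2 * k * (k + 1) / r**2, v * k * (k + 1) / r**2)
    else:  # exp_drift_diffusion
        v, D = float(params["v"]), float(params["D"])
        if D < 0:
            raise ValidationError("diffusivity must be >= 0")
        m = (1 / r, 2 / r**2, v / r, 2 * v**2 / r**2 + 2 * D / r, 2 * v / r**2)

    clean = {k: float(val) for k, val in params.items()}
    law = StateLaw(family=family, params=clean,
                   **dict(zip(_MOMENT_KEYS, (float(x) for x in m))))
    law.validate()
    return law


class SwitchingModel:
    """A semi-Markov switching process: embedded chain plus per-state laws.

    Parameters
    ----------
    P : (n, n) row-stochastic matrix with zero diagonal (the embedded chain).
    laws : one :class:`StateLaw` per state.
    base_state : index of the regeneration state.
    labels : optional state names.

    States unreachable from the base state never contribute to regeneration
    cycles; they are pruned on construction with a logged warning. The model
    must return to base with probability one (spectral radius of the
    substochastic restriction of ``P`` below 1), otherwise construction fails.
    """

    def __init__(self, P, laws: Sequence[StateLaw], base_state: int = 0,
                 labels: Sequence[str] | None = None):
        P = np.array(P, dtype=float)
        laws = list(laws)
        n = P.shape[0]
        if P.shape != (n, n) or len(laws) != n:
            raise ValidationError("P must be square with one law per state")
        if not 0 <= base_state < n:
            raise ValidationError("base_state out of range")
        if n == 1:
            # degenerate model: the self-transition is the return to base
            if abs(P[0, 0] - 1.0) > 1e-12:
                raise ValidationError("one-state model requires P = [[1]]")
        else:
            if np.any(np.abs(np.diag(P)) > 0):
                raise ValidationError("P must have zero diagonal")
            if np.any(P < -1e-15):
                raise ValidationError("P must be non-negative")
            row_err = np.abs(P.sum(axis=1) - 1.0)
            if np.any(row_err > 1e-9):
                raise ValidationError("rows of P must sum to 1")
        for i, law in enumerate(laws):
            try:
                law.validate()
            except ValidationError as e:
                raise ValidationError(f"law of state {i}: {e}") from e

        # prune states unreachable from base
        reachable = _reachable_from(P, base_state)
        if not reachable.all():
            dropped = np.flatnonzero(~reachable)
            logger.warning("pruning states unreachable from base: %s",
                           dropped.tolist())
            keep = np.flatnonzero(reachable)
            P = P[np.ix_(keep, keep)]
            P = P / P.sum(axis=1, keepdims=True)
            laws = [laws[i] for i in keep]
            if labels is not None:
                labels = [labels[i] for i in keep]
            base_state = int(np.searchsorted(keep, base_state))
            n = len(keep)

        self.P = P
        self.laws = laws
        self.base_state = int(base_state)
        self.labels = list(labels) if labels is not None else None
        self.n_states = n

        rad = self.substochastic_radius()
        if rad >= 1.0 - 1e-9:
            raise ValidationError(
                f"chain is not recurrent to base state {base_state}: "
                f"spectral radius of the non-base restriction is {rad:.6g}"
            )

    # -- structure ---------------------------------------------------------
    @property
    def non_base(self) -> np.ndarray:
        """Indices of the non-base states, in state order."""
        return np.array([i for i in range(self.n_states) if i != self.base_state],
                        dtype=int)

    @property
    def P_tilde(self) -> np.ndarray:
        """Substochastic restriction of P to the non-base states."""
        nb = self.non_base
        return self.P[np.ix_(nb, nb)]

    @property
    def p1(self) -> np.ndarray:
        """First-step probabilities out of the base state (base row of P,
        restricted to non-base states)."""
        return self.P[self.base_state, self.non_base]

    def substochastic_radius(self) -> float:
        pt = self.P_tilde
        if pt.size == 0:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(pt))))

    def with_base(self, base_state: int) -> "SwitchingModel":
        """Same process, regeneration marked by a different base state."""
        return SwitchingModel(self.P, self.laws, base_state, self.labels)

    def law_moment_vectors(self):
        """Per-state moment arrays (E_tau, E_tau2, E_xi, E_xi2, E_tauxi)."""
        m = np.array([law.moments for law in self.laws])
        return tuple(m[:, j] for j in range(5))

    def __repr__(self) -> str:
        return (f"SwitchingModel(n_states={self.n_states}, "
                f"base_state={self.base_state})")


def _reachable_from(P: np.ndarray, start: int) -> np.ndarray:
    n = P.shape[0]
    reach = np.zeros(n, bool)
    reach[start] = True
    frontier = [start]
    adj = P > 0
    while frontier:
        nxt = np.flatnonzero(adj[frontier].any(axis=0) & ~reach)
        reach[nxt] = True
        frontier = nxt.tolist()
    return reach


@dataclass(frozen=True)
class RateMatrix:
    """CTMC generator with per-state velocities and diffusivities.

    ``A`` has non-negative off-diagonal rates (1/s) and zero row sums;
    ``v`` (µm/s) and ``d`` (µm²/s, >= 0) are the state transport coefficients.
    """

    A: np.ndarray
    v: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        A = np.array(self.A, dtype=float)
        v = np.array(self.v, dtype=float)
        d = np.array(self.d, dtype=float)
        n = A.shape[0]
        if A.shape != (n, n) or v.shape != (n,) or d.shape != (n,):
            raise ValidationError("A must be square; v, d matching vectors")
        off = A - np.diag(np.diag(A))
        if np.any(off < -1e-12):
            raise ValidationError("off-diagonal rates must be >= 0")
        scale = max(1.0, float(np.abs(A).max()))
        if np.any(np.abs(A.sum(axis=1)) > 1e-9 * scale):
            raise ValidationError("rows of A must sum to zero")
        if np.any(d < 0):
            raise ValidationError("diffusivities must be >= 0")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "d", d)

    @classmethod
    def from_rates(cls, off_rates, v, d) -> "RateMatrix":
        """Build from off-diagonal rates; the diagonal is filled in."""
        R = np.array(off_rates, dtype=float)
        np.fill_diagonal(R, 0.0)
        A = R - np.diag(R.sum(axis=1))
        return cls(A, np.asarray(v, float), np.asarray(d, float))

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def exit_rates(self) -> np.ndarray:
        A = self.A
        return A.sum(axis=1) - np.diag(A)  # = -diag(A) given zero row sums

    def check_irreducible(self) -> None:
        n, comp = connected_components(self.A > 0, directed=True,
                                       connection="strong")
        if n > 1:
            sizes = np.bincount(comp)
            minority = np.flatnonzero(comp != np.argmax(sizes)).tolist()
            raise ValidationError(
                f"rate matrix is reducible; states {minority} do not "
                "communicate with the rest"
            )


def stationary_distribution(rm: RateMatrix) -> np.ndarray:
    """Stationary distribution pi of the CTMC: pi^T A = 0, sum(pi) = 1.

    Solved as a constrained linear system (A^T stacked with the normalization
    row), not by eigen-iteration.
    """
    rm.check_irreducible()
    n = rm.n_states
    M = np.vstack([rm.A.T, np.ones((1, n))])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    if np.any(pi <= 0):
        raise ValidationError("stationary distribution has non-positive mass "
                              "(chain effectively reducible)")
    return pi


def embed_ctmc(rm: RateMatrix, base_state: int = 0) -> SwitchingModel:
    """Embed a CTMC switching diffusion as a :class:`SwitchingModel`.

    The jump chain has ``P_ij = A_ij / lambda_i`` off the diagonal with
    ``lambda_i`` the total exit rate of state i, and state i's sojourn is
    Exp(lambda_i). The displacement law per state follows from its transport
    coefficients: pure drift, pure diffusion, a pause, or the combined
    ``v tau + sqrt(2 d tau) Z`` law when both are nonzero.
    """
    rm.check_irreducible()
    lam = rm.exit_rates
    if np.any(lam <= 0):
        bad = np.flatnonzero(lam <= 0).tolist()
        raise ValidationError(f"absorbing states {bad}: chain not recurrent")
    P = rm.A / lam[:, None]
    np.fill_diagonal(P, 0.0)
    P = np.clip(P, 0.0, None)

    laws = []
    for i in range(rm.n_states):
        v_i, d_i = float(rm.v[i]), float(rm.d[i])
        if v_i == 0.0 and d_i == 0.0:
            laws.append(make_state_law("exp_pause", r=lam[i]))
        elif d_i == 0.0:
            laws.append(make_state_law("exp_drift", r=lam[i], v=v_i))
        elif v_i == 0.0:
            laws.append(make_state_law("exp_diffusion", r=lam[i], D=d_i))
        else:
            laws.append(make_state_law("exp_drift_diffusion",
                                       r=lam[i], v=v_i, D=d_i))
    return SwitchingModel(P, laws, base_state=base_state)
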