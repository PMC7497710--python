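"""Homogenization oracle for CTMC switching diffusions.

For a particle whose state follows an irreducible CTMC with generator ``A``
and whose transport in state i is advection ``v_i`` plus diffusion ``d_i``,
the forward Kolmogorov system reduces at large scales to a scalar
advection-diffusion equation with

    v_eff = v . pi
    D_eff = d . pi - v . x,   where  A^T x = v o pi - v_eff pi,  sum(x) = 0,

``pi`` the stationary distribution and ``o`` the Hadamard product. The
right-hand side sums to zero by construction, so the restricted inverse of
``A^T`` (on vectors orthogonal to 1) is well defined; it is realized here as
a bordered KKT system rather than a pseudoinverse.

This route is fully independent of the renewal-reward cycle recursions and
serves as a cross-check for the CTMC subclass of models.
"""

from __future__ import annotations

import numpy as np

from .cycle_moments import EffectiveTransport
from .switching_model import RateMatrix, ValidationError, stationary_distribution

__all__ = ["homogenized_transport"]


def homogenized_transport(rm: RateMatrix) -> EffectiveTransport:
    """Effective velocity and diffusivity of a CTMC switching diffusion."""
    pi = stationary_distribution(rm)
    v, d = rm.v, rm.d
    v_eff = float(v @ pi)

    b = v * pi - v_eff * pi
    if abs(b.sum()) > 1e-10 * max(1.0, float(np.abs(v).max())):
        raise ValidationError("internal consistency failure: homogenization "
                              "right-hand side does not sum to zero")

    n = rm.n_states
    # bordered system pins the solution branch with sum(x) = 0
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = rm.A.T
    M[:n, n] = 1.0
    M[n, :n] = 1.0
    rhs = np.concatenate([b, [0.0]])
    x = np.linalg.solve(M, rhs)[:n]

    D_eff = float(d @ pi - v @ x)
    return EffectiveTransport(v_eff=v_eff, D_eff=D_eff, run_length=float("nan"),
                              cycle_stats=None)
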