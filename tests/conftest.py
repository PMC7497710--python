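"""Shared fixtures: random model factories and Monte-Carlo error bars."""

from __future__ import annotations

import numpy as np
import pytest

from regencycle import RateMatrix, SwitchingModel, make_state_law

LAW_FAMILIES = ("exp_drift", "exp_diffusion", "exp_pause", "gamma_drift",
                "exp_drift_diffusion")


def random_rate_matrix(rng: np.random.Generator, n: int,
                       rate_range=(0.01, 0.1)) -> RateMatrix:
    """Dense random irreducible CTMC with mixed drift/diffusion states."""
    R = rng.uniform(*rate_range, (n, n))
    v = rng.uniform(-1.0, 1.0, n)
    d = rng.uniform(0.0, 1.0, n)
    return RateMatrix.from_rates(R, v, d)


def random_law(rng: np.random.Generator, family: str | None = None):
    family = family or rng.choice(LAW_FAMILIES)
    r = rng.uniform(0.2, 2.0)
    v = rng.uniform(-1.0, 1.0)
    if family == "exp_drift":
        return make_state_law("exp_drift", r=r, v=v)
    if family == "exp_diffusion":
        return make_state_law("exp_diffusion", r=r, D=rng.uniform(0.1, 1.0))
    if family == "exp_pause":
        return make_state_law("exp_pause", r=r)
    if family == "gamma_drift":
        return make_state_law("gamma_drift", k=rng.uniform(0.5, 4.0), r=r, v=v)
    return make_state_law("exp_drift_diffusion", r=r, v=v,
                          D=rng.uniform(0.1, 1.0))


def random_semi_markov(rng: np.random.Generator, n: int,
                       families=None) -> SwitchingModel:
    """Random embedded chain with mixed sojourn/displacement families."""
    P = rng.uniform(0.1, 1.0, (n, n))
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    laws = [random_law(rng, families[i] if families else None)
            for i in range(n)]
    return SwitchingModel(P, laws, base_state=0)


def random_four_state(rng: np.random.Generator) -> SwitchingModel:
    """Diffusive/forward/backward/paused particle with uniform random rates."""
    from regencycle import build_four_state

    return build_four_state(rng.uniform(0.01, 0.1, (4, 4)),
                            v_plus=rng.uniform(0.1, 1.0),
                            v_minus=rng.uniform(0.1, 1.0),
                            D=rng.uniform(0.1, 1.0))


# -- Monte-Carlo standard errors -------------------------------------------

def se_mean(x) -> float:
    x = np.asarray(x)
    return float(x.std(ddof=1) / np.sqrt(x.size))


def se_var(x) -> float:
    """SE of the sample variance via the fourth central moment."""
    x = np.asarray(x)
    n = x.size
    m4 = np.mean((x - x.mean()) ** 4)
    s2 = x.var(ddof=1)
    return float(np.sqrt(max(m4 - s2**2 * (n - 3) / (n - 1), 0.0) / n))


def se_cov(x, y) -> float:
    """SE of the sample covariance (delta-method)."""
    x, y = np.asarray(x), np.asarray(y)
    n = x.size
    cx, cy = x - x.mean(), y - y.mean()
    c = np.sum(cx * cy) / (n - 1)
    m22 = np.mean(cx**2 * cy**2)
    return float(np.sqrt(max(m22 - c**2, 0.0) / n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
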