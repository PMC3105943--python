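"""The three-component minimal model of the community effect.

Each of n identical cells carries two proteins, x and y; y is exported into a
shared extracellular pool z, and z feeds back to activate synthesis of x —
the smallest possible intercellular positive feedback, with no transcription
step.  Synthesis follows Michaelis–Menten kinetics without cooperativity,
and the model tracks volumes explicitly: V_c per cell and V_s for the whole
system (extracellular volume = V_s - n*V_c, which must stay positive).

With identical cells the system reduces to

    dx/dt = k1 * z/(K_z+z) - delta1 * x
    dy/dt = k2 * x/(K_x+x) - delta2 * y
    dz/dt = k3~ * y/(K_y+y) - delta3 * z,   k3~ = n*k3*V_c/(V_s - n*V_c)

where V_c/(V_s - n*V_c) converts per-cell export into extracellular
concentration.  The dimensionless gain is xi = k1*k2*k3/(delta1*delta2*delta3);
with unit Michaelis constants the linearized loop gain around the origin is
xi * n*V_c/(V_s - n*V_c), giving the critical community size

    n_c = V_s / (V_c * (xi + 1))

and critical cell density eta_c = n_c*V_c/V_s = 1/(xi+1).  For xi >> 1,
n_c is proportional to 1/xi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MinimalParams",
    "MinimalThreshold",
    "MinimalSteadyState",
    "minimal_rhs",
    "minimal_threshold",
    "minimal_steady_state",
    "minimal_sweep",
]


@dataclass(frozen=True)
class MinimalParams:
    """Rates, volumes and half-saturation constants of the minimal model.

    Defaults are the canonical plotting regime: k = 0.02, delta = 0.01,
    V_c = 1, V_s = 800 (so xi = 8 and n_c = 800/9).  The Michaelis constants
    default to 1 in the model's concentration units; only then does the
    threshold reduce to a formula in xi alone.
    """

    k1: float = 0.02
    k2: float = 0.02
    k3: float = 0.02
    delta1: float = 0.01
    delta2: float = 0.01
    delta3: float = 0.01
    V_c: float = 1.0
    V_s: float = 800.0
    n: int = 1
    K_x: float = 1.0
    K_y: float = 1.0
    K_z: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "delta1", "delta2", "delta3",
                     "V_c", "V_s", "K_x", "K_y", "K_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.V_s <= self.n * self.V_c:
            raise ValueError(
                f"system volume V_s={self.V_s} must exceed total cell volume "
                f"n*V_c={self.n * self.V_c}")

    def replace(self, **changes) -> "MinimalParams":
        return replace(self, **changes)

    @property
    def k3_eff(self) -> float:
        """n*k3*V_c/(V_s - n*V_c): per-pool export rate of n cells."""
        return self.n * self.k3 * self.V_c / (self.V_s - self.n * self.V_c)


@dataclass(frozen=True)
class MinimalThreshold:
    xi: float       # k1*k2*k3 / (delta1*delta2*delta3)
    n_c: float      # critical community size (cells, real-valued)
    eta_c: float    # critical cell density n_c*V_c/V_s


@dataclass(frozen=True)
class MinimalSteadyState:
    x: float
    y: float
    z: float
    regime: str  # "quiescent" | "active"


def minimal_rhs(state, params: MinimalParams) -> np.ndarray:
    x, y, z = np.asarray(state, dtype=float)
    if min(x, y, z) < 0:
        raise ValueError("state must be non-negative")
    p = params
    return np.array([
        p.k1 * z / (p.K_z + z) - p.delta1 * x,
        p.k2 * x / (p.K_x + x) - p.delta2 * y,
        p.k3_eff * y / (p.K_y + y) - p.delta3 * z,
    ])


def _origin_gain(params: MinimalParams, n: float) -> float:
    """Linearized loop gain around the all-zero state at community size n."""
    p = params
    dilution = n * p.V_c / (p.V_s - n * p.V_c)
    return (p.k1 / (p.delta1 * p.K_z)) * (p.k2 / (p.delta2 * p.K_x)) \
        * (p.k3 / (p.delta3 * p.K_y)) * dilution


def minimal_threshold(params: MinimalParams) -> MinimalThreshold:
    """xi, n_c and eta_c.

    n_c solves loop-gain = 1.  With unit Michaelis constants the closed form
    n_c = V_s/(V_c*(xi+1)) applies; otherwise n_c is found by bisection on the
    (monotone) linearized gain over n in (0, V_s/V_c).
    """
    p = params
    xi = (p.k1 * p.k2 * p.k3) / (p.delta1 * p.delta2 * p.delta3)
    if p.K_x == p.K_y == p.K_z == 1.0:
        n_c = p.V_s / (p.V_c * (xi + 1.0))
    else:
        hi = p.V_s / p.V_c
        n_c = brentq(lambda n: _origin_gain(p, n) - 1.0, 1e-12 * hi, hi * (1 - 1e-12))
    return MinimalThreshold(xi=xi, n_c=n_c, eta_c=n_c * p.V_c / p.V_s)


def minimal_steady_state(params: MinimalParams) -> MinimalSteadyState:
    """Non-trivial fixed point when it exists, else the origin.

    The fixed-point equations collapse to one scalar equation z = g(z) with g
    increasing and bounded (g(inf) = k3~/delta3 * ...), so the non-trivial
    root is bracketed and found with Brent's method.  The origin is always a
    fixed point; the community is active when the linearized gain there
    exceeds 1, i.e. when n > n_c.
    """
    p = params

    def g(z: float) -> float:
        x = (p.k1 / p.delta1) * z / (p.K_z + z)
        y = (p.k2 / p.delta2) * x / (p.K_x + x)
        return (p.k3_eff / p.delta3) * y / (p.K_y + y)

    if _origin_gain(p, p.n) <= 1.0:
        return MinimalSteadyState(0.0, 0.0, 0.0, regime="quiescent")
    z_hi = p.k3_eff / p.delta3  # g(z) < z_hi for all z
    # g(z) - z is positive just above 0 (gain > 1) and negative at z_hi
    lo = 1e-12 * max(z_hi, 1.0)
    while g(lo) - lo <= 0 and lo < z_hi:
        lo *= 10.0
    z = brentq(lambda s: g(s) - s, lo, z_hi, xtol=1e-14, rtol=1e-13)
    x = (p.k1 / p.delta1) * z / (p.K_z + z)
    y = (p.k2 / p.delta2) * x / (p.K_x + x)
    return MinimalSteadyState(x, y, z, regime="active")


def minimal_sweep(params: MinimalParams, n_values) -> "pd.DataFrame":
    """Steady state of x as a function of community size."""
    import pandas as pd

    rows = []
    for n in n_values:
        ss = minimal_steady_state(params.replace(n=int(n)))
        rows.append({"n": int(n), "x": ss.x, "y": ss.y, "z": ss.z, "regime": ss.regime})
    return pd.DataFrame(rows)
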