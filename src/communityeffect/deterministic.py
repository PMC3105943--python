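"""Deterministic dynamics of the full transcription model.

In the deterministic (mean-field) regime all cells are identical, so the
community reduces to one representative cell plus the shared extracellular
pool — an 8-variable ODE system in

    (Ac, Am, Ap, Ba, Bm, Bp_in, Bp_out, Cp).

The reduced system has a closed-form fixed point.  Writing K = alpha2/alpha1
for the promoter dissociation constant, P_A = a*beta*gamma/(delta_m*delta_a)
and P_B = b*beta*gamma/(delta_m*(kappa+delta_b)) for the saturated protein
levels, and

    D_n = P_B * (n*kappa / (n*eps + delta_d)) * (eps / delta_c)

for the communication gain of n cells, the activator level at the
self-sustaining steady state is

    Cp* = max(0, (D_n * P_A - K^2) / (P_A + K)),

from which every other species follows down the cascade.  Cp* > 0 (an active
community) exactly when n exceeds the critical community size

    n_c = delta_d / (eps * (a*b*rho - 1)),

where rho is the dimensionless loop gain of the cascade (see
:func:`communityeffect.core.derived_constants`); a*b*rho > 1 is necessary
for a community effect at any finite size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import FullModelParams, derived_constants

__all__ = [
    "STATE_VARS",
    "SteadyState",
    "CriticalSize",
    "rhs",
    "integrate",
    "steady_state",
    "steady_state_limit",
    "critical_size",
    "sweep",
]

STATE_VARS = ("Ac", "Am", "Ap", "Ba", "Bm", "Bp_in", "Bp_out", "Cp")

# Promoter variables are O(1) while Bp_out reaches O(1e5): tight tolerances
# keep the small variables meaningful.
RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message carries its diagnostics."""


@dataclass(frozen=True)
class SteadyState:
    """Closed-form fixed point of the reduced deterministic system."""

    Ac_s: float
    Am_s: float
    Ap_s: float
    Ba_s: float
    Bm_s: float
    Bp_in_s: float
    Bp_out_s: float
    Cp_s: float
    regime: str  # "quiescent" | "active"

    def as_array(self) -> np.ndarray:
        return np.array([self.Ac_s, self.Am_s, self.Ap_s, self.Ba_s,
                         self.Bm_s, self.Bp_in_s, self.Bp_out_s, self.Cp_s])

    def to_dict(self) -> dict:
        d = {k: getattr(self, f"{k}_s") for k in
             ("Ac", "Am", "Ap", "Ba", "Bm", "Bp_in", "Bp_out", "Cp")}
        d["regime"] = self.regime
        return d


@dataclass(frozen=True)
class CriticalSize:
    """Threshold community size for a self-sustaining (active) steady state."""

    n_c: float        # real-valued root; inf when infeasible
    n_c_int: int | None  # smallest integer community strictly above threshold
    feasible: bool    # a*b*rho > 1


def rhs(state, params: FullModelParams) -> np.ndarray:
    """Time derivative of the reduced community state.

    The shared pool gains ``n*kappa*Bp_in`` because every one of the n
    identical cells exports, and loses ``n*eps*Bp_out`` because every cell is
    an equal sink.  With ``sequester_activator`` the bound activator is held
    on the promoter (the binding terms move molecules of Cp and Ap); the
    fixed point is unchanged because binding and unbinding balance there.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (8,):
        raise ValueError(f"expected 8 state variables {STATE_VARS}, got shape {y.shape}")
    if np.any(y < 0):
        raise ValueError("state must be non-negative")
    p = params
    Ac, Am, Ap, Ba, Bm, Bp_in, Bp_out, Cp = y
    bindA = p.alpha1 * Cp * (p.a - Ac)
    unbindA = p.alpha2 * Ac
    bindB = p.alpha1 * Ap * (p.b - Ba)
    unbindB = p.alpha2 * Ba
    dAc = bindA - unbindA
    dAm = p.beta * Ac - p.delta_m * Am
    dAp = p.gamma * Am - p.delta_a * Ap
    dBa = bindB - unbindB
    dBm = p.beta * Ba - p.delta_m * Bm
    dBp_in = p.gamma * Bm - (p.kappa + p.delta_b) * Bp_in
    dBp_out = p.n * p.kappa * Bp_in - (p.n * p.epsilon + p.delta_d) * Bp_out
    dCp = p.epsilon * Bp_out - p.delta_c * Cp
    if p.sequester_activator:
        dCp += unbindA - bindA
        dAp += unbindB - bindB
    return np.array([dAc, dAm, dAp, dBa, dBm, dBp_in, dBp_out, dCp])


def default_initial(params: FullModelParams) -> np.ndarray:
    """Both genes off, no molecules except the extracellular inducer pulse."""
    y0 = np.zeros(8)
    y0[6] = params.bp_out_init
    return y0


def integrate(
    params: FullModelParams,
    t_end: float,
    initial=None,
    t_eval=None,
    method: str = "LSODA",
    rtol: float = RTOL,
    atol: float = ATOL,
) -> pd.DataFrame:
    """Integrate the reduced ODE system to ``t_end`` seconds.

    Returns a tidy trajectory table with a ``time`` column (seconds) and one
    column per state variable, on ``t_eval`` if given else on a uniform
    200-point grid.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    y0 = default_initial(params) if initial is None else np.asarray(initial, dtype=float)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    sol = solve_ivp(
        lambda t, y: rhs(np.maximum(y, 0.0), params),
        (0.0, float(t_end)),
        y0,
        method=method,
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    df = pd.DataFrame(sol.y.T, columns=list(STATE_VARS))
    df.insert(0, "time", sol.t)
    return df


def steady_state(params: FullModelParams) -> SteadyState:
    """Closed-form steady state of the reduced system.

    Independent of the initial condition (in particular of ``bp_out_init``):
    the induction pulse only triggers the transition, it does not shape the
    fixed point.
    """
    c = derived_constants(params)
    return _steady_state_from_gain(params, c.D_n, c.K, c.P_A)


def steady_state_limit(params: FullModelParams) -> SteadyState:
    """The n -> infinity limit of the steady state.

    As the community grows, n*kappa/(n*eps + delta_d) -> kappa/eps, so the
    communication gain saturates at D_inf = P_B*kappa/delta_c.  Ap* saturates
    with it, while Bp_out* = delta_c*Cp*/eps approaches its (much larger)
    theoretical ceiling.
    """
    c = derived_constants(params)
    return _steady_state_from_gain(params, c.D_inf, c.K, c.P_A)


def _steady_state_from_gain(params, D, K, P_A) -> SteadyState:
    p = params
    Cp_s = max(0.0, (D * P_A - K * K) / (P_A + K)) if P_A > 0 else 0.0
    if Cp_s <= 0.0:
        return SteadyState(0, 0, 0, 0, 0, 0, 0, 0, regime="quiescent")
    Ap_s = P_A * Cp_s / (Cp_s + K)
    Ac_s = p.a * Cp_s / (Cp_s + K)
    Am_s = p.beta * Ac_s / p.delta_m
    Ba_s = p.b * Ap_s / (Ap_s + K)
    Bm_s = p.beta * Ba_s / p.delta_m
    Bp_in_s = p.gamma * Bm_s / (p.kappa + p.delta_b)
    Bp_out_s = p.delta_c * Cp_s / p.epsilon
    return SteadyState(Ac_s, Am_s, Ap_s, Ba_s, Bm_s, Bp_in_s, Bp_out_s, Cp_s,
                       regime="active")


def critical_size(params: FullModelParams) -> CriticalSize:
    """Critical community size n_c = delta_d / (eps*(a*b*rho - 1)).

    Equivalently the n at which the active branch appears (D_n*P_A = K^2).
    Infeasible (n_c = inf) when a*b*rho <= 1: no community of any size can
    sustain activation.  ``n_c_int`` = floor(n_c) + 1 is the smallest integer
    community strictly above threshold.
    """
    c = derived_constants(params)
    gain = params.a * params.b * c.rho
    if gain <= 1.0 or params.epsilon <= 0:
        return CriticalSize(n_c=math.inf, n_c_int=None, feasible=False)
    n_c = params.delta_d / (params.epsilon * (gain - 1.0))
    return CriticalSize(n_c=n_c, n_c_int=int(math.floor(n_c)) + 1, feasible=True)


def sweep(params: FullModelParams, axis: str, values) -> pd.DataFrame:
    """Steady state as a function of ``n``, ``epsilon`` or ``delta_d``.

    Returns one row per axis value with the eight steady-state variables, the
    regime, and a ``first_active`` flag on the first value whose steady state
    is active.  ``n`` may be real-valued here (the closed form is continuous);
    integer n is only required for simulation.
    """
    if axis not in ("n", "epsilon", "delta_d"):
        raise ValueError(f"axis must be one of n/epsilon/delta_d, got {axis!r}")
    values = list(values)
    if not values or any(v <= 0 for v in values):
        raise ValueError("sweep values must be non-empty and positive")
    c = derived_constants(params)
    rows = []
    for v in values:
        if axis == "n":
            # the closed form is continuous in n; evaluate it at real-valued v
            ss = _steady_state_from_gain(params, _gain_at(params, v), c.K, c.P_A)
        else:
            ss = steady_state(params.replace(**{axis: float(v)}))
        row = {axis: v}
        row.update(ss.to_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    active = df["regime"].eq("active")
    df["first_active"] = False
    if active.any():
        df.loc[active.idxmax(), "first_active"] = True
    return df


def _gain_at(params: FullModelParams, n: float) -> float:
    """Communication gain D_n for a (possibly non-integer) community size."""
    c = derived_constants(params)
    return c.P_B * (n * params.kappa / (n * params.epsilon + params.delta_d)) \
        * (params.epsilon / params.delta_c)
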