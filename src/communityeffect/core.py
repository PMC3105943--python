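"""Parameter sets, state containers, derived constants and the reaction network.

The full transcription model is a linear cascade of two genes per cell,
A (a transcription factor, the Xbra analogue) and B (a secreted signalling
ligand, the FGF4 analogue), closed into a positive feedback loop *through the
population*: the protein of gene B is exported into a single extracellular
pool shared by all ``n`` cells, taken up by any cell and converted into the
activator Cp, which switches on gene A.  There is no intracellular feedback;
the loop only closes via the shared pool, which is why its behaviour depends
on the community size.

All species are absolute molecule numbers per cell in a unit volume (the
extracellular pool ``Bp_out`` is a single global count), so deterministic
concentrations and stochastic counts are numerically comparable without any
volume conversion.  All rate constants are in s^-1 (first-order) or
s^-1 per molecule (the promoter-binding rate alpha1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "TABLE1_RATES",
    "EPSILON_FAST",
    "EPSILON_SLOW",
    "FullModelParams",
    "CellState",
    "CommunityState",
    "DerivedConstants",
    "Channel",
    "ReactionNetwork",
    "make_default_params",
    "derived_constants",
    "build_network",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

MINUTE = 60.0  # seconds

#: Canonical kinetic rates (s^-1) of the full transcription model.
TABLE1_RATES: Mapping[str, float] = {
    "alpha1": 1.93e-4,   # activator binding to promoter (per activator molecule)
    "alpha2": 3.47e-2,   # activator dissociation from promoter
    "beta": 1.16e-2,     # transcription per active gene
    "gamma": 2.31e-2,    # translation per mRNA
    "delta_m": 1.16e-3,  # mRNA degradation
    "delta_a": 3.47e-4,  # Ap degradation
    "delta_b": 3.47e-4,  # Bp_in degradation
    "delta_c": 3.47e-4,  # Cp degradation
    "delta_d": 3.47e-4,  # Bp_out decay / loss
    "kappa": 3.85e-4,    # exocytosis (export of Bp_in)
}

#: The two canonical communication rates (s^-1).
EPSILON_FAST = 2.31e-6
EPSILON_SLOW = 5.78e-7

_RATE_FIELDS = (
    "alpha1", "alpha2", "beta", "gamma", "delta_m",
    "delta_a", "delta_b", "delta_c", "delta_d", "kappa", "epsilon",
)

#: Per-cell species, in the order used by flat state vectors.
CELL_SPECIES = ("Ac", "Am", "Ap", "Ba", "Bm", "Bp_in", "Cp")


class ValidationError(ValueError):
    """A parameter set violates a model invariant."""


@dataclass(frozen=True)
class FullModelParams:
    """Kinetic rates, gene copy numbers and community configuration.

    A zero rate is permitted and switches the corresponding reaction off
    (used for reduced sub-networks such as a pure-decay calibration);
    negative rates are rejected.  ``sequester_activator`` controls whether
    promoter binding consumes the activator molecule (holds it on the
    promoter) or acts catalytically; the deterministic steady state is
    identical either way.
    """

    alpha1: float = TABLE1_RATES["alpha1"]
    alpha2: float = TABLE1_RATES["alpha2"]
    beta: float = TABLE1_RATES["beta"]
    gamma: float = TABLE1_RATES["gamma"]
    delta_m: float = TABLE1_RATES["delta_m"]
    delta_a: float = TABLE1_RATES["delta_a"]
    delta_b: float = TABLE1_RATES["delta_b"]
    delta_c: float = TABLE1_RATES["delta_c"]
    delta_d: float = TABLE1_RATES["delta_d"]
    kappa: float = TABLE1_RATES["kappa"]
    epsilon: float = EPSILON_SLOW
    a: int = 1              # gene A copy number
    b: int = 1              # gene B copy number
    n: int = 1              # community size (cells)
    bp_out_init: int = 500  # extracellular Bp at t = 0 (the inducer pulse)
    sequester_activator: bool = False

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"rate constant {name!r} must be finite and >= 0, got {v}")
        if int(self.n) != self.n or self.n < 1:
            raise ValidationError(f"community size n must be an integer >= 1, got {self.n}")
        for name in ("a", "b"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"gene copy number {name!r} must be an integer >= 0, got {v}")
        if int(self.bp_out_init) != self.bp_out_init or self.bp_out_init < 0:
            raise ValidationError(f"bp_out_init must be an integer >= 0, got {self.bp_out_init}")

    def replace(self, **changes) -> "FullModelParams":
        return dataclasses.replace(self, **changes)


def make_default_params(
    epsilon: float = EPSILON_SLOW,
    n: int = 1,
    a: int = 1,
    b: int = 1,
    **overrides,
) -> FullModelParams:
    """Canonical parameter set: Table-1 rates, 500 inducer molecules at t=0.

    ``epsilon`` is normally one of :data:`EPSILON_FAST` / :data:`EPSILON_SLOW`;
    any strictly positive value is accepted as an explicit choice.  Rate
    overrides must be strictly positive here — build a
    :class:`FullModelParams` directly to switch a reaction off.
    """
    if not np.isfinite(epsilon) or epsilon <= 0:
        raise ValidationError(f"epsilon must be > 0, got {epsilon}")
    for key, v in overrides.items():
        if key in _RATE_FIELDS and (not np.isfinite(v) or v <= 0):
            raise ValidationError(f"rate constant {key!r} must be > 0, got {v}")
    return FullModelParams(epsilon=epsilon, n=n, a=a, b=b, **overrides)


@dataclass
class CellState:
    """Per-cell molecule counts (integer in the SSA, real in the ODE limit)."""

    Ac: float = 0.0      # active gene-A promoters, 0..a
    Am: float = 0.0      # gene-A mRNA
    Ap: float = 0.0      # A protein
    Ba: float = 0.0      # active gene-B promoters, 0..b
    Bm: float = 0.0      # gene-B mRNA
    Bp_in: float = 0.0   # intracellular B protein
    Cp: float = 0.0      # converted activator

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in CELL_SPECIES], dtype=float)


@dataclass
class CommunityState:
    """Full state: n cells plus the shared extracellular pool and a clock."""

    cells: Sequence[CellState]
    Bp_out: float = 0.0
    t: float = 0.0

    @property
    def n(self) -> int:
        return len(self.cells)

    def ap_counts(self) -> np.ndarray:
        return np.array([c.Ap for c in self.cells], dtype=float)

    def active_fraction(self) -> float:
        """Percentage of cells with at least one Ap molecule."""
        return 100.0 * float(np.mean(self.ap_counts() > 0))


@dataclass(frozen=True)
class DerivedConstants:
    """Constants of the closed-form steady state.

    K is the promoter dissociation constant; P_A and P_B are the saturated
    (fully active promoter) protein levels including gene copy numbers;
    rho is the dimensionless loop gain — the product of all forward cascade
    rates over all reverse/degradation rates, independent of epsilon,
    delta_d, n and the copy numbers; D_n is the communication gain of a
    community of n cells (molecules of Cp at activator saturation).
    """

    K: float
    P_A: float
    P_B: float
    rho: float
    D_n: float
    D_inf: float


def derived_constants(params: FullModelParams) -> DerivedConstants:
    p = params
    K = p.alpha2 / p.alpha1
    P_A = p.a * p.beta * p.gamma / (p.delta_m * p.delta_a)
    P_B = p.b * p.beta * p.gamma / (p.delta_m * (p.kappa + p.delta_b))
    rho = (p.alpha1**2 * p.beta**2 * p.gamma**2 * p.kappa) / (
        p.alpha2**2 * p.delta_m**2 * p.delta_a * (p.kappa + p.delta_b) * p.delta_c
    )
    if p.epsilon > 0:
        D_n = P_B * (p.n * p.kappa / (p.n * p.epsilon + p.delta_d)) * (p.epsilon / p.delta_c)
    else:
        D_n = 0.0
    D_inf = P_B * p.kappa / p.delta_c
    return DerivedConstants(K=K, P_A=P_A, P_B=P_B, rho=rho, D_n=D_n, D_inf=D_inf)


# ---------------------------------------------------------------------------
# Declarative reaction network
# ---------------------------------------------------------------------------
#
# Propensity specs are small tuples so that both the reference SSA and the
# mean-field consistency tests can evaluate them at arbitrary (real-valued)
# states:
#   ("lin",  rate, i)              -> rate * x[i]
#   ("bind", rate, act, prom, cn)  -> rate * x[act] * (cn - x[prom])

@dataclass(frozen=True)
class Channel:
    name: str
    deltas: tuple  # ((species index, integer delta), ...)
    prop: tuple

    def propensity(self, x: np.ndarray) -> float:
        kind = self.prop[0]
        if kind == "lin":
            return self.prop[1] * x[self.prop[2]]
        # bind
        _, rate, act, prom, cn = self.prop
        return rate * x[act] * (cn - x[prom])


@dataclass(frozen=True)
class ReactionNetwork:
    """Flattened channel list for an n-cell community.

    The state vector is ``[cell0 species..., cell1 species..., ..., Bp_out]``
    with per-cell species ordered as :data:`CELL_SPECIES`.
    """

    params: FullModelParams
    species_index: Mapping
    channels: tuple

    @property
    def n_species(self) -> int:
        return 7 * self.params.n + 1

    @property
    def pool_index(self) -> int:
        return 7 * self.params.n

    def propensities(self, x: np.ndarray) -> np.ndarray:
        return np.array([c.propensity(x) for c in self.channels], dtype=float)

    def stoich_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.channels), self.n_species))
        for k, ch in enumerate(self.channels):
            for idx, d in ch.deltas:
                S[k, idx] = d
        return S

    def drift(self, x: np.ndarray) -> np.ndarray:
        """Mean-field right-hand side: sum of delta x propensity per species."""
        return self.stoich_matrix().T @ self.propensities(x)

    def initial_state(self) -> np.ndarray:
        x = np.zeros(self.n_species)
        x[self.pool_index] = self.params.bp_out_init
        return x


def build_network(params: FullModelParams) -> ReactionNetwork:
    """Enumerate the 15*n + 1 channels of the full model.

    Per cell: A-promoter bind/unbind, A transcription, Am decay, A translation,
    Ap decay, B-promoter bind/unbind, B transcription, Bm decay, B translation,
    Bp_in decay, Bp_in export, uptake of Bp_out into Cp, Cp decay; plus one
    global Bp_out decay.  Uptake carries propensity eps*Bp_out per cell, so the
    total uptake propensity is n*eps*Bp_out (every cell is an equal sink).
    """
    p = params
    pool = 7 * p.n
    idx = {}
    for i in range(p.n):
        for j, s in enumerate(CELL_SPECIES):
            idx[(i, s)] = 7 * i + j
    idx["Bp_out"] = pool

    seq = p.sequester_activator
    channels = []
    for i in range(p.n):
        Ac, Am, Ap = idx[(i, "Ac")], idx[(i, "Am")], idx[(i, "Ap")]
        Ba, Bm, Bp_in, Cp = idx[(i, "Ba")], idx[(i, "Bm")], idx[(i, "Bp_in")], idx[(i, "Cp")]
        bindA_d = ((Ac, +1), (Cp, -1)) if seq else ((Ac, +1),)
        unbindA_d = ((Ac, -1), (Cp, +1)) if seq else ((Ac, -1),)
        bindB_d = ((Ba, +1), (Ap, -1)) if seq else ((Ba, +1),)
        unbindB_d = ((Ba, -1), (Ap, +1)) if seq else ((Ba, -1),)
        channels += [
            Channel(f"bindA[{i}]", bindA_d, ("bind", p.alpha1, Cp, Ac, p.a)),
            Channel(f"unbindA[{i}]", unbindA_d, ("lin", p.alpha2, Ac)),
            Channel(f"txA[{i}]", ((Am, +1),), ("lin", p.beta, Ac)),
            Channel(f"decAm[{i}]", ((Am, -1),), ("lin", p.delta_m, Am)),
            Channel(f"translA[{i}]", ((Ap, +1),), ("lin", p.gamma, Am)),
            Channel(f"decAp[{i}]", ((Ap, -1),), ("lin", p.delta_a, Ap)),
            Channel(f"bindB[{i}]", bindB_d, ("bind", p.alpha1, Ap, Ba, p.b)),
            Channel(f"unbindB[{i}]", unbindB_d, ("lin", p.alpha2, Ba)),
            Channel(f"txB[{i}]", ((Bm, +1),), ("lin", p.beta, Ba)),
            Channel(f"decBm[{i}]", ((Bm, -1),), ("lin", p.delta_m, Bm)),
            Channel(f"translB[{i}]", ((Bp_in, +1),), ("lin", p.gamma, Bm)),
            Channel(f"decBpin[{i}]", ((Bp_in, -1),), ("lin", p.delta_b, Bp_in)),
            Channel(f"export[{i}]", ((Bp_in, -1), (pool, +1)), ("lin", p.kappa, Bp_in)),
            Channel(f"uptake[{i}]", ((pool, -1), (Cp, +1)), ("lin", p.epsilon, pool)),
            Channel(f"decCp[{i}]", ((Cp, -1),), ("lin", p.delta_c, Cp)),
        ]
    channels.append(Channel("decBpout", ((pool, -1),), ("lin", p.delta_d, pool)))
    return ReactionNetwork(params=p, species_index=idx, channels=tuple(channels))


# ---------------------------------------------------------------------------
# Config serialization (flat YAML key:value; JSON is a YAML subset and loads too)
# ---------------------------------------------------------------------------

def params_to_dict(params: FullModelParams) -> dict:
    return dataclasses.asdict(params)


def params_from_dict(d: Mapping) -> FullModelParams:
    known = {f.name for f in dataclasses.fields(FullModelParams)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
    return FullModelParams(**d)


def save_params(params: FullModelParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def load_params(path) -> FullModelParams:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))
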