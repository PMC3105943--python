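"""Experiment drivers, fixtures and the diffusion-uniformity check.

Presets reproduce the canonical figures/tables of the model at a requested
``scale`` (fraction of the full replicate count), writing CSV/JSON artifacts
plus a manifest that records the fully resolved parameters and seeds so any
run can be reproduced bit for bit.  Durations in this module are quoted in
minutes (the natural unit for these timescales) and converted to seconds
internally; all rates are s^-1.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    EPSILON_FAST,
    EPSILON_SLOW,
    FullModelParams,
    make_default_params,
    params_to_dict,
)
from .deterministic import critical_size, integrate, steady_state, steady_state_limit, sweep
from .minimal import MinimalParams, minimal_sweep, minimal_threshold
from .stochastic import ensemble, noise_table

__all__ = [
    "ExperimentSpec",
    "DiffusionCheck",
    "PRESETS",
    "run_experiment",
    "diffusion_uniformity",
    "make_fixture",
    "FIXTURE_SPEEDUP",
]

MIN = 60.0  # seconds per minute

STEADY_STATE_EVAL_MIN = 10_000   # steady-state evaluation time (minutes)
TRANSIENT_EVAL_MIN = 3_000       # transient evaluation time (minutes)
FULL_ENSEMBLE_RUNS = 100         # replicate count at scale = 1

PRESETS = ("fig2b", "fig4", "fig5", "fig6", "fig7", "table2", "custom")


@dataclass
class ExperimentSpec:
    """A named experiment at a given scale, with parameter overrides."""

    name: str
    output_dir: Path
    scale: float = 1.0
    overrides: dict = field(default_factory=dict)
    seed_base: int = 0

    def __post_init__(self) -> None:
        if self.name not in PRESETS:
            raise ValueError(f"unknown preset {self.name!r}; choose from {PRESETS}")
        if not (0 < self.scale <= 1.0):
            raise ValueError(f"scale must be in (0, 1], got {self.scale}")
        self.output_dir = Path(self.output_dir)


@dataclass(frozen=True)
class DiffusionCheck:
    """Is a secreted ligand effectively uniform across a spherical tissue?

    A ligand with diffusion coefficient D (um^2/s) and decay rate
    k = ln2 / half-life explores a characteristic decay length
    sqrt(D/k) before disappearing; when that length is at least the tissue
    radius, concentration gradients across the tissue are mild and the
    equal-sink assumption of the community model holds.
    """

    D: float              # um^2/s
    half_life: float      # minutes
    decay_rate: float     # s^-1
    decay_length: float   # um
    tissue_radius: float  # um
    uniform: bool


def diffusion_uniformity(D: float, half_life: float, tissue_radius: float) -> DiffusionCheck:
    """Decay-length test of the well-mixed-pool assumption.

    The measured reference values for FGF8 are D = 91 um^2/s and an 18-minute
    half-life, giving a decay length of roughly 376 um — larger than a
    typical embryonic cell-community radius of ~100 um.
    """
    if D <= 0 or half_life <= 0 or tissue_radius <= 0:
        raise ValueError("all arguments must be positive")
    k = math.log(2.0) / (half_life * MIN)
    L = math.sqrt(D / k)
    return DiffusionCheck(D=D, half_life=half_life, decay_rate=k,
                          decay_length=L, tissue_radius=tissue_radius,
                          uniform=L >= tissue_radius)


# ---------------------------------------------------------------------------
# fast fixtures
# ---------------------------------------------------------------------------

#: All kinetic rates are multiplied by this factor in fixtures, compressing
#: time 100-fold while leaving the dimensionless gain rho, the copy-number
#: threshold structure and all steady-state molecule numbers unchanged.
FIXTURE_SPEEDUP = 100.0

_FIXTURE_NC = 8.0  # target critical size of the sped-up regime


def make_fixture(regime: str) -> FullModelParams:
    """Small, fast parameter sets preserving the model's qualitative regimes.

    Uniformly scaling every rate constant by :data:`FIXTURE_SPEEDUP` leaves
    rho invariant (seven rate factors in both numerator and denominator), so
    the threshold physics is untouched; epsilon is then chosen so that
    n_c = 8 cells, and n is placed well below, well above, or just above it:

    * ``fast-quiescent`` — n = 4 < n_c: the community always dies out.
    * ``fast-active``    — n = 32 >> n_c: reliable activation in ~minutes of
      simulated time.
    * ``near-threshold`` — n = 10, (n - n_c)/n_c = 0.25: bistable outcomes
      (a run either extinguishes or settles near the active steady state).
    """
    regimes = {"fast-active": 32, "fast-quiescent": 4, "near-threshold": 10}
    if regime not in regimes:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(regimes)}")
    from .core import TABLE1_RATES
    scaled = {k: v * FIXTURE_SPEEDUP for k, v in TABLE1_RATES.items()}
    base = FullModelParams(**scaled, epsilon=1.0, n=1)
    from .core import derived_constants
    rho = derived_constants(base).rho
    eps = scaled["delta_d"] / (_FIXTURE_NC * (rho - 1.0))
    params = FullModelParams(**scaled, epsilon=eps, n=regimes[regime])
    cs = critical_size(params)
    assert cs.feasible and abs(cs.n_c - _FIXTURE_NC) < 1e-9
    return params


def fixture_t_end(params: FullModelParams) -> float:
    """A steady-state evaluation horizon for fixture runs (seconds):
    the canonical 10000 minutes compressed by the fixture speed-up."""
    return STEADY_STATE_EVAL_MIN * MIN / FIXTURE_SPEEDUP


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def run_experiment(spec: ExperimentSpec) -> dict:
    """Run a preset and write its artifacts; returns the manifest."""
    out = spec.output_dir
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    n_runs = max(1, round(FULL_ENSEMBLE_RUNS * spec.scale))
    param_fields = {f.name for f in dataclasses.fields(FullModelParams)}
    param_overrides = {k: v for k, v in spec.overrides.items() if k in param_fields}
    base = None if spec.name == "fig2b" else make_default_params(
        **{"epsilon": EPSILON_SLOW, **param_overrides})

    files: list[str] = []
    extra: dict = {}

    if spec.name == "fig2b":
        mp = MinimalParams(**{k: v for k, v in spec.overrides.items()
                              if k in {f.name for f in dataclasses.fields(MinimalParams)}})
        thr = minimal_threshold(mp)
        n_grid = range(1, int(mp.V_s / mp.V_c))
        df = minimal_sweep(mp, n_grid)
        df.to_csv(out / "fig2b_steady_state_vs_n.csv", index=False)
        files.append("fig2b_steady_state_vs_n.csv")
        extra = {"xi": thr.xi, "n_c": thr.n_c, "eta_c": thr.eta_c}

    elif spec.name == "fig4":
        files, extra = _run_fig4(spec, base, out, n_runs)

    elif spec.name == "fig5":
        files, extra = _run_fig5(spec, base, out, n_runs)

    elif spec.name == "fig6":
        rows = []
        n_grid = spec.overrides.get("n_grid", list(range(10, 501, 10)))
        for a, b in [(2, 2), (1, 2), (2, 1), (1, 1)]:
            p = base.replace(a=a, b=b)
            sw = sweep(p, "n", n_grid)
            sw.insert(0, "a", a)
            sw.insert(1, "b", b)
            lim = steady_state_limit(p)
            sw["Ap_limit"] = lim.Ap_s
            sw["Bp_out_limit"] = lim.Bp_out_s
            rows.append(sw)
        df = pd.concat(rows, ignore_index=True)
        df.to_csv(out / "fig6_steady_state_vs_n_by_copy_number.csv", index=False)
        files.append("fig6_steady_state_vs_n_by_copy_number.csv")
        extra = {"Bp_out_limits": {f"a{a}b{b}": steady_state_limit(base.replace(a=a, b=b)).Bp_out_s
                                   for a, b in [(2, 2), (1, 2), (2, 1), (1, 1)]}}

    elif spec.name == "fig7":
        axes = {"epsilon": np.geomspace(1e-7, 1e-5, 60),
                "delta_d": np.geomspace(3.47e-5, 3.47e-2, 60)}
        for axis, values in axes.items():
            frames = []
            for n in spec.overrides.get("n_values", [50, 100, 200, 500]):
                sw = sweep(base.replace(n=int(n)), axis, values)
                sw.insert(0, "n", int(n))
                frames.append(sw)
            name = f"fig7_steady_state_vs_{axis}.csv"
            pd.concat(frames, ignore_index=True).to_csv(out / name, index=False)
            files.append(name)

    elif spec.name == "table2":
        rows = [(200, EPSILON_FAST), (200, EPSILON_SLOW),
                (300, EPSILON_SLOW), (500, EPSILON_SLOW)]
        df = noise_table(base, rows, STEADY_STATE_EVAL_MIN * MIN, n_runs, spec.seed_base)
        df.to_csv(out / "table2_noise.csv", index=False)
        files.append("table2_noise.csv")
        extra = {"rows": df.to_dict(orient="records")}

    else:  # custom: deterministic steady-state + critical-size summary
        cs = critical_size(base)
        ss = steady_state(base)
        summary = {"critical_size": {"n_c": cs.n_c, "n_c_int": cs.n_c_int,
                                     "feasible": cs.feasible},
                   "steady_state": ss.to_dict()}
        with open(out / "custom_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        files.append("custom_summary.json")
        extra = summary

    manifest = {
        "preset": spec.name,
        "package_version": __version__,
        "scale": spec.scale,
        "n_runs": n_runs,
        "scaled": spec.scale < 1.0,
        "seed_base": spec.seed_base,
        "overrides": {k: v for k, v in spec.overrides.items()},
        "params": params_to_dict(base) if base is not None else None,
        "units": {"time": "seconds", "rates": "s^-1", "species": "molecules"},
        "runtime_s": None,
        "files": files,
        "results": _jsonable(extra),
    }
    manifest["runtime_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_fig4(spec, base, out, n_runs):
    """ODE time courses, the deterministic steady-state curve, and the
    stochastic temperature map at n = 300."""
    t_end = spec.overrides.get("t_end_min", STEADY_STATE_EVAL_MIN) * MIN
    files = []
    frames = []
    for n in spec.overrides.get("n_values", [50, 300, 500]):
        tr = integrate(base.replace(n=int(n)), t_end)
        tr.insert(0, "n", int(n))
        frames.append(tr)
    pd.concat(frames, ignore_index=True).to_csv(out / "fig4ab_ode_trajectories.csv",
                                                index=False)
    files.append("fig4ab_ode_trajectories.csv")

    n_grid = list(range(10, 501, 10))
    curves = []
    for eps in (EPSILON_FAST, EPSILON_SLOW):
        sw = sweep(base.replace(epsilon=eps), "n", n_grid)
        sw.insert(0, "epsilon", eps)
        curves.append(sw)
    pd.concat(curves, ignore_index=True).to_csv(out / "fig4c_steady_state_vs_n.csv",
                                                index=False)
    files.append("fig4c_steady_state_vs_n.csv")

    n_map = int(spec.overrides.get("map_n", 300))
    snaps = np.linspace(0, t_end, 101)
    ens = ensemble(base.replace(n=n_map), t_end, n_runs, spec.seed_base,
                   snapshot_times=snaps)
    ens.temperature_map().to_csv(out / "fig4de_temperature_map.csv")
    files.append("fig4de_temperature_map.csv")
    return files, {"map_mean_ap": ens.mean, "map_noise": ens.noise}


def _run_fig5(spec, base, out, n_runs):
    """Active-cell-fraction histograms over a grid of community sizes."""
    t_end = spec.overrides.get("t_end_min", STEADY_STATE_EVAL_MIN) * MIN
    t_mid = spec.overrides.get("t_mid_min", TRANSIENT_EVAL_MIN) * MIN
    combos = spec.overrides.get(
        "combos",
        [{"epsilon": EPSILON_SLOW, "a": 1, "b": 1},
         {"epsilon": EPSILON_FAST, "a": 1, "b": 1},
         {"epsilon": EPSILON_SLOW, "a": 2, "b": 2},
         {"epsilon": EPSILON_SLOW, "a": 1, "b": 2}],
    )
    rows = []
    for ci, combo in enumerate(combos):
        p0 = base.replace(**{k: v for k, v in combo.items() if k != "n_grid"})
        n_c = critical_size(p0).n_c
        n_grid = combo.get("n_grid") or spec.overrides.get("n_grid") \
            or _fig5_grid(n_c)
        for nj, n in enumerate(n_grid):
            p = p0.replace(n=int(n))
            ens = ensemble(p, t_end, n_runs,
                           spec.seed_base + 1000 * ci + nj,
                           snapshot_times=[t_mid, t_end])
            for r in range(n_runs):
                rows.append({
                    "epsilon": p.epsilon, "a": p.a, "b": p.b, "n": int(n),
                    "n_c": n_c, "run": r,
                    "active_pct_mid": ens.snapshot_active_fraction[r, 0],
                    "active_pct_end": ens.snapshot_active_fraction[r, 1],
                })
    df = pd.DataFrame(rows)
    df.to_csv(out / "fig5_active_fraction.csv", index=False)
    return ["fig5_active_fraction.csv"], {
        "n_combos": len(combos), "runs_per_point": n_runs}


def _fig5_grid(n_c: float) -> list:
    """Community sizes straddling the threshold, one clearly below."""
    lo = max(1, int(0.5 * n_c))
    return sorted({lo, int(n_c) + 5, int(1.5 * n_c), int(2 * n_c), int(5 * n_c)})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
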