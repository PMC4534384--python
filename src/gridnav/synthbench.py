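"""Synthetic scenario generation, noise models, and the cross-model harness.

The generator emulates the idealized encoding conditions of the decoders:
noise-free modular phase codes for pairs of locations whose displacement
lies within half the system capacity, optionally perturbed by von Mises
phase jitter (circular analogue of Gaussian noise on a phase estimate) or
Gaussian rate noise truncated at zero. The canonical worked examples —
scales {50, 30, 20} cm with displacements 75 cm and (75, 37.5) cm along
the axes, and scales {30, 20} cm with a goal 30 cm ahead — ship as
fixtures.

``run_matrix`` runs every decoder on every scenario and tabulates
per-axis circular errors (the displacement code is only defined modulo
the system period C, so estimate and truth are compared on the circle),
a success flag against each model's a-priori error bound, and look-ahead
latencies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gridcode import (
    GridSystem,
    Location,
    PhaseCode,
    from_scales,
    encode_location,
    phase_difference,
    project_onto_axes,
    wrap_phase,
)
from . import algsolve
from .algsolve import system_period
from .distance_cells import DistanceCellModel
from .vector_cells_rate import RateVectorCellModel
from .vector_cells_phase import PhaseVectorCellModel
from .lookahead import LookaheadModel

MODEL_NAMES = ("algorithmic", "distance", "vector_rate", "vector_phase", "lookahead")

#: CSV schema of the evaluation table.
EVAL_COLUMNS = (
    "scenario_id", "model", "true_dx", "true_dy",
    "est_dx", "est_dy", "error_cm", "success", "latency_steps",
)


@dataclass(frozen=True)
class NoiseSpec:
    """phase_kappa: von Mises concentration (None/inf = noise-free);
    rate_sigma: s.d. of additive Gaussian rate noise, truncated at 0."""

    phase_kappa: float | None = None
    rate_sigma: float | None = None


@dataclass(frozen=True)
class Scenario:
    scenario_id: str
    system: GridSystem
    start: Location
    goal: Location
    noise: NoiseSpec | None = None
    seed: int = 0


@dataclass(frozen=True)
class EvalRecord:
    scenario_id: str
    model: str
    decoded: np.ndarray  # cartesian (dx, dy)
    true: np.ndarray
    error_cm: float
    success: bool
    latency_steps: int | None = None


def canonical_system() -> GridSystem:
    """The canonical three-module system: scales {50, 30, 20} cm."""
    return from_scales([50.0, 30.0, 20.0])


def two_module_system() -> GridSystem:
    """The two-module system of the phase-coded example: {30, 20} cm."""
    return from_scales([30.0, 20.0])


def worked_example_fixtures() -> list[Scenario]:
    """The canonical worked-example scenarios.

    1. 1D: scales {50,30,20}, displacement 75 cm along axis 1.
    2. 2D: same scales, displacement (75, 37.5) cm along the axes.
    3. Phase model: scales {30,20}, current 0, goal 30 cm.
    4. Phase model, shifted pair: current 45 cm, goal 75 cm.
    """
    sys3 = canonical_system()
    sys2 = two_module_system()
    B3 = sys3.basis

    def loc(system_basis, u, v):
        xy = system_basis @ np.array([u, v])
        return Location(float(xy[0]), float(xy[1]))

    return [
        Scenario("1d-75", sys3, loc(B3, 0, 0), loc(B3, 75, 0)),
        Scenario("2d-75-37.5", sys3, loc(B3, 0, 0), loc(B3, 75, 37.5)),
        Scenario("phase-goal-30", sys2, loc(sys2.basis, 0, 0), loc(sys2.basis, 30, 0)),
        Scenario("phase-shift-45-75", sys2, loc(sys2.basis, 45, 0), loc(sys2.basis, 75, 0)),
    ]


def random_scenarios(
    system: GridSystem,
    n: int,
    seed: int,
    noise: NoiseSpec | None = None,
    work_area: float | None = None,
) -> list[Scenario]:
    """n random start/goal pairs, uniform displacement within capacity/2.

    Starts are uniform over a square work area (default: one capacity
    square); axis-coordinate displacements are uniform in (−C/2, C/2) per
    axis. Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    C = min(system_period(system, axis=0), system_period(system, axis=1))
    if work_area is None:
        work_area = C
    B = system.basis
    out = []
    for j in range(n):
        start = rng.uniform(0.0, work_area, size=2)
        duv = rng.uniform(-C / 2, C / 2, size=2)
        goal = start + B @ duv
        out.append(
            Scenario(
                scenario_id=f"rand-{j:04d}",
                system=system,
                start=Location(float(start[0]), float(start[1])),
                goal=Location(float(goal[0]), float(goal[1])),
                noise=noise,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


def perturb(code: PhaseCode, noise: NoiseSpec | None, rng_or_seed) -> PhaseCode:
    """Apply von Mises phase jitter to a code; identity if noise-free.

    A concentration κ corresponds roughly to Gaussian jitter of s.d.
    1/√κ rad for large κ. Deterministic under the given seed/generator.
    """
    if noise is None or noise.phase_kappa is None or not math.isfinite(noise.phase_kappa):
        return code
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    jitter = rng.vonmises(0.0, noise.phase_kappa, size=code.phases.shape)
    return PhaseCode(wrap_phase(code.phases + jitter))


def perturb_rates(rates: np.ndarray, sigma: float, rng_or_seed) -> np.ndarray:
    """Additive Gaussian rate noise, truncated at zero."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    return np.maximum(0.0, rates + rng.normal(0.0, sigma, size=rates.shape))


class AlgorithmicModel:
    """Thin wrapper giving the plane-fit solver the common decode interface."""

    name = "algorithmic"

    def __init__(self, system: GridSystem):
        self.system = system

    def decode(self, code_a: PhaseCode, code_b: PhaseCode):
        dp = phase_difference(code_a, code_b)
        return algsolve.decode_2d_planefit(dp, self.system).vector

    def axis_error_bound(self, axis: int) -> float:
        return 1e-6


_MODEL_FACTORIES = {
    "algorithmic": AlgorithmicModel,
    "distance": DistanceCellModel,
    "vector_rate": RateVectorCellModel,
    "vector_phase": PhaseVectorCellModel,
    "lookahead": LookaheadModel,
}


def build_models(system: GridSystem, names=MODEL_NAMES) -> dict:
    """Instantiate the requested decoders (weights/tables built once)."""
    unknown = set(names) - set(_MODEL_FACTORIES)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    return {name: _MODEL_FACTORIES[name](system) for name in names}


def success_tolerance(model, system: GridSystem, axis: int) -> float:
    """Per-axis success tolerance: max(model error bound, s_M/4)."""
    return max(model.axis_error_bound(axis), float(system.axis_scales(axis).min()) / 4.0)


def _circ_cm(delta: float, C: float) -> float:
    """Signed difference wrapped to [−C/2, C/2)."""
    return float(np.mod(delta + C / 2.0, C) - C / 2.0)


def run_matrix(
    scenarios: list[Scenario],
    models=MODEL_NAMES,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run every decoder on every scenario; tabulate errors and latencies.

    Per-axis errors are circular (modulo the system period). Writes
    ``evaluation.csv`` and ``summary.json`` under ``out_dir`` if given;
    outputs are byte-identical across runs with fixed seeds.
    """
    cache: dict[int, dict] = {}
    rows = []
    for sc in scenarios:
        key = id(sc.system)
        if key not in cache:
            cache[key] = build_models(sc.system, models)
        mdl = cache[key]
        code_a = encode_location(sc.start, sc.system)
        code_b = encode_location(sc.goal, sc.system)
        if sc.noise is not None:
            rng = np.random.default_rng(sc.seed)
            code_a = perturb(code_a, sc.noise, rng)
            code_b = perturb(code_b, sc.noise, rng)
        du = np.subtract(
            project_onto_axes(sc.goal, sc.system),
            project_onto_axes(sc.start, sc.system),
        )
        C = [system_period(sc.system, axis=a) for a in (0, 1)]
        B = sc.system.basis
        true_cart = B @ du
        for name, model in mdl.items():
            vec = model.decode(code_a, code_b)
            err_axis = np.array(
                [_circ_cm(vec.axis_components[a] - du[a], C[a]) for a in (0, 1)]
            )
            err_cm = float(np.linalg.norm(B @ err_axis))
            ok = all(
                abs(err_axis[a]) <= success_tolerance(model, sc.system, a)
                for a in (0, 1)
            )
            latency = None
            if name == "lookahead" and model.last_latency is not None:
                latency = model.last_latency["latency_steps"]
            rows.append(
                {
                    "scenario_id": sc.scenario_id,
                    "model": name,
                    "true_dx": true_cart[0],
                    "true_dy": true_cart[1],
                    "est_dx": vec.cartesian[0],
                    "est_dy": vec.cartesian[1],
                    "error_cm": err_cm,
                    "success": bool(ok),
                    "latency_steps": latency,
                }
            )
    df = pd.DataFrame(rows, columns=list(EVAL_COLUMNS))
    summary = {}
    for name, grp in df.groupby("model", sort=True):
        entry = {
            "n": int(len(grp)),
            "success_rate": float(grp["success"].mean()),
            "mean_error_cm": float(grp["error_cm"].mean()),
            "max_error_cm": float(grp["error_cm"].max()),
        }
        if name == "lookahead":
            lat = grp["latency_steps"].dropna()
            if len(lat):
                entry["mean_latency_steps"] = float(lat.mean())
        summary[name] = entry
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "evaluation.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return df, summary
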