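"""The linear look-ahead decoder.

Rather than decoding the displacement directly, the grid network can
simulate constant-speed movement away from the current location along an
axis, decoupled from real motion: each module's phase advances at a rate
inversely proportional to its scale (faster for smaller modules), exactly
as during path integration. When the advanced phases coincide with the
goal code in every module simultaneously — detectable by a conjunctive
coincidence unit such as the goal's place cell — the sweep stops, and the
number of steps taken (or the activity accumulated by an integrator
neuron over the event) encodes the distance. Latency is therefore
proportional to distance: the model's defining behavioural prediction.

The sweep operates on phase codes directly (an abstract attractor bump);
during a sweep along one axis, phases on the other axis are untouched, so
the co-active cells form phase "bands" aligned with the swept axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .gridcode import (
    TWO_PI,
    GridSystem,
    PhaseCode,
    TranslationVector,
    circ_dist,
)
from .algsolve import system_period


@dataclass(frozen=True)
class SweepResult:
    """Outcome of one unidirectional look-ahead sweep."""

    axis: int
    direction: int  # ±1
    detected: bool
    distance: float  # cm at detection (= steps × step_size)
    steps: int
    integrator: float  # accumulated readout activity, monotone in steps


def default_step(system: GridSystem, axis: int = 0) -> float:
    """Step so that even the smallest module advances ≪ π/4 per step."""
    return float(system.axis_scales(axis).min()) / 40.0


def default_tolerance(system: GridSystem, axis: int = 0) -> float:
    """Coincidence tolerance: half the phase-bin width of the smallest module."""
    i = int(np.argmin(system.axis_scales(axis)))
    return math.pi / system.modules[i].cells_per_axis


def sweep(
    system: GridSystem,
    code_start: PhaseCode,
    code_target: PhaseCode,
    axis: int = 0,
    direction: int = 1,
    step_size: float | None = None,
    max_distance: float | None = None,
    tol: float | None = None,
) -> SweepResult:
    """Advance the start code along one axis until it matches the target.

    Every module's axis phase advances by 2π·step/s_i per step; coincidence
    fires at the first step where the circular phase error to the target is
    within ``tol`` in all modules at once. ``detected`` is False if no
    coincidence occurs within ``max_distance`` (default: half the system
    period, which covers every unambiguous displacement).
    """
    if direction not in (1, -1):
        raise ValueError("direction must be ±1")
    scales = system.axis_scales(axis)
    if step_size is None:
        step_size = default_step(system, axis)
    if step_size > float(scales.min()) / 8 + 1e-12:
        raise ValueError("step_size must be ≤ s_M/8")
    if max_distance is None:
        max_distance = system_period(system, axis=axis) / 2.0
    if tol is None:
        tol = default_tolerance(system, axis)
    p0 = code_start.phases[:, axis]
    pt = code_target.phases[:, axis]
    n_steps = int(round(max_distance / step_size))
    k = np.arange(n_steps + 1)
    phases = p0[None, :] + direction * TWO_PI * step_size * k[:, None] / scales[None, :]
    err = circ_dist(phases, pt[None, :]).max(axis=1)
    hits = np.flatnonzero(err <= tol)
    # A step-0 hit is legitimate for targets within the coincidence window;
    # it signals a mis-sized tolerance only when the target is clearly
    # several sweep steps away in the smallest module's phase metric.
    step0_window = 2.0 * TWO_PI * step_size / float(scales.min())
    if hits.size and hits[0] == 0 and float(circ_dist(p0, pt).max()) > step0_window:
        warnings.warn(
            "coincidence tolerance fires at step 0 for distinct codes; "
            "tol is too large for this step size",
            stacklevel=2,
        )
    if hits.size == 0:
        return SweepResult(
            axis=axis,
            direction=direction,
            detected=False,
            distance=math.nan,
            steps=n_steps,
            integrator=float(n_steps),
        )
    steps = int(hits[0])
    return SweepResult(
        axis=axis,
        direction=direction,
        detected=True,
        distance=steps * step_size,
        steps=steps,
        integrator=float(steps),
    )


def sweep_from_goal(
    system: GridSystem,
    code_goal: PhaseCode,
    code_current: PhaseCode,
    axis: int = 0,
    direction: int = 1,
    **kwargs,
) -> SweepResult:
    """Sweep initiated from the goal, searching for the current location.

    Identical contract with the roles reversed: the detected distance along
    ``direction`` equals the forward sweep's distance with the sign of the
    implied displacement negated.
    """
    return sweep(system, code_goal, code_current, axis=axis, direction=direction, **kwargs)


def _signed_axis_sweep(
    system: GridSystem,
    code_a: PhaseCode,
    code_b: PhaseCode,
    axis: int,
    step_size: float | None,
    tol: float | None,
) -> tuple[float, int]:
    """Bidirectional sweep on one axis; returns (signed distance, steps)."""
    fwd = sweep(system, code_a, code_b, axis=axis, direction=1,
                step_size=step_size, tol=tol)
    bwd = sweep(system, code_a, code_b, axis=axis, direction=-1,
                step_size=step_size, tol=tol)
    if not (fwd.detected or bwd.detected):
        raise ValueError(f"no coincidence found on axis {axis}")
    if fwd.detected and (not bwd.detected or fwd.steps <= bwd.steps):
        return fwd.distance, fwd.steps
    return -bwd.distance, bwd.steps


def decode_vector_2d(
    system: GridSystem,
    code_a: PhaseCode,
    code_b: PhaseCode,
    step_size: float | None = None,
    tol: float | None = None,
) -> tuple[TranslationVector, dict]:
    """Bidirectional sweeps on both axes; nearer coincidence sets the sign.

    Returns the assembled translation vector and latency diagnostics
    (steps per axis and total).
    """
    if not system.shared_axes:
        raise ValueError("look-ahead 2D decoding requires shared axes")
    d = []
    steps = []
    for axis in (0, 1):
        dist, st = _signed_axis_sweep(system, code_a, code_b, axis, step_size, tol)
        d.append(dist)
        steps.append(st)
    vec = TranslationVector(d[0], d[1], basis=system.basis)
    diag = {"steps_axis1": steps[0], "steps_axis2": steps[1],
            "latency_steps": steps[0] + steps[1]}
    return vec, diag


class LookaheadModel:
    """Sweep-based decoder with a fixed step size, reusable across decodes."""

    name = "lookahead"

    def __init__(
        self,
        system: GridSystem,
        step_size: float | None = None,
        tol: float | None = None,
    ):
        if not system.shared_axes:
            raise ValueError("look-ahead decoding requires shared axes")
        self.system = system
        self.step_size = {
            axis: step_size if step_size is not None else default_step(system, axis)
            for axis in (0, 1)
        }
        self.tol = {
            axis: tol if tol is not None else default_tolerance(system, axis)
            for axis in (0, 1)
        }
        self.last_latency: dict | None = None

    def decode(self, code_a: PhaseCode, code_b: PhaseCode) -> TranslationVector:
        d = []
        steps = []
        for axis in (0, 1):
            dist, st = _signed_axis_sweep(
                self.system, code_a, code_b, axis,
                self.step_size[axis], self.tol[axis],
            )
            d.append(dist)
            steps.append(st)
        self.last_latency = {
            "steps_axis1": steps[0],
            "steps_axis2": steps[1],
            "latency_steps": steps[0] + steps[1],
        }
        return TranslationVector(d[0], d[1], basis=self.system.basis)

    def axis_error_bound(self, axis: int) -> float:
        """A-priori per-axis error: the coincidence window in cm."""
        s_min = float(self.system.axis_scales(axis).min())
        return self.tol[axis] * s_min / TWO_PI + self.step_size[axis] / 2.0
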