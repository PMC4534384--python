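"""The phase-coded vector-cell decoder.

Grid cells undergo theta phase precession: as the animal crosses a firing
field, spikes arrive progressively earlier relative to the 5–11 Hz theta
rhythm. If precession is linear, aligned with one axis, and spans the
full theta cycle — π rad at field entry, 0 at the field centre, −π at the
exit — then the theta firing phase of a goal-coding grid cell equals the
(wrapped) spatial phase difference between goal and current location in
its module. The vector of theta phases across modules within a single
theta cycle therefore encodes the displacement to the goal, irrespective
of the current location, and template matching against the phase vectors
of candidate displacements decodes it directly.

Spikes here are abstract (module, theta-phase) events; the model's
content is the phase mapping, not spike generation, so no oscillator or
Poisson machinery is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gridcode import (
    TWO_PI,
    GridModule,
    GridSystem,
    PhaseCode,
    TranslationVector,
    circ_dist,
    phase_difference,
    wrap_signed,
)
from .algsolve import system_period


@dataclass(frozen=True)
class ThetaFrame:
    """Reference theta oscillation: frequency (Hz) and current cycle phase.

    Phase 0 is the trough, where current-location cells fire.
    """

    theta_frequency: float = 8.0
    cycle_phase: float = 0.0

    def __post_init__(self):
        if not (5.0 <= self.theta_frequency <= 11.0):
            raise ValueError("theta frequency must lie in [5, 11] Hz")
        if not (-math.pi < self.cycle_phase <= math.pi):
            raise ValueError("cycle phase must lie in (−π, π]")


@dataclass(frozen=True)
class PhasedSpike:
    """One goal-coding grid cell's spike within a theta cycle."""

    module: int
    axis: int
    cell_offset: float  # the cell's spatial phase (its field position)
    theta_phase: float  # rad in (−π, π]
    goal_id: int = 0

    def __post_init__(self):
        if not (-math.pi < self.theta_phase <= math.pi):
            raise ValueError("theta phase must lie in (−π, π]")


def precession_phase(dp_axis: float, module: GridModule | None = None) -> float:
    """Theta firing phase of a goal-coding cell at spatial phase diff Δp.

    The mapping is linear with unit slope in phase units (the module scale
    enters only through Δp itself): Δp ∈ [0, 2π) wraps onto (−π, π], so the
    current-location cell (Δp = 0) fires at the trough (0 rad) and a goal
    less than half a scale ahead fires at a later (positive) phase.
    """
    return float(wrap_signed(dp_axis))


def emit_theta_cycle(
    system: GridSystem,
    code_a: PhaseCode,
    goal_codes,
    axis: int = 0,
) -> list[PhasedSpike]:
    """Spikes of all active goal-coding cells in one theta cycle.

    One spike per goal per module, at the precession phase of that goal's
    spatial phase difference from the current code along the axis. Multiple
    goals coexist in the cycle with distinct phase patterns, so the
    distance to every known goal on the axis is broadcast each cycle.
    """
    spikes: list[PhasedSpike] = []
    for gid, code_b in enumerate(goal_codes):
        dp = phase_difference(code_a, code_b)
        for i in range(system.n_modules):
            spikes.append(
                PhasedSpike(
                    module=i,
                    axis=axis,
                    cell_offset=float(code_b.phases[i, axis]),
                    theta_phase=precession_phase(dp.dphases[i, axis]),
                    goal_id=gid,
                )
            )
    return spikes


def default_resolution(system: GridSystem, axis: int = 0) -> float:
    return float(system.axis_scales(axis).min()) / 4.0


def displacement_templates(
    system: GridSystem, axis: int = 0, resolution: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement bins over (−C/2, C/2] and their theta-phase templates.

    The half-open range is closed on the positive side so a displacement of
    exactly half the capacity is reported with positive sign. Template for
    displacement d: per module, wrap(2πd/s_i) into (−π, π].
    """
    C = system_period(system, axis=axis)
    if not math.isfinite(C):
        raise ValueError("system capacity is infinite")
    if resolution is None:
        resolution = default_resolution(system, axis)
    n = round(C / resolution)
    bins = -C / 2.0 + resolution * np.arange(1, n + 1)
    scales = system.axis_scales(axis)
    templates = wrap_signed(TWO_PI * bins[:, None] / scales[None, :])
    return bins, templates


@dataclass(frozen=True)
class PhaseDecodeResult:
    displacement: float
    score: float  # summed squared circular phase error, rad²
    ambiguous: bool


def phase_template_decode(
    spikes: list[PhasedSpike],
    system: GridSystem,
    axis: int = 0,
    resolution: float | None = None,
    ambiguity_tol: float = 1e-9,
) -> dict[int, PhaseDecodeResult]:
    """Decode the displacement to each goal from its theta-phase vector.

    Spikes are grouped by goal tag; each goal's per-module phase vector is
    matched against the displacement templates by summed squared circular
    distance. Exact to the bin resolution on noise-free phases. If two
    templates match within ``ambiguity_tol``, the smaller |d| is returned
    and the result is flagged ambiguous.
    """
    bins, templates = displacement_templates(system, axis=axis, resolution=resolution)
    by_goal: dict[int, dict[int, float]] = {}
    for sp in spikes:
        if sp.axis != axis:
            continue
        by_goal.setdefault(sp.goal_id, {})[sp.module] = sp.theta_phase
    out: dict[int, PhaseDecodeResult] = {}
    for gid, phases in sorted(by_goal.items()):
        vec = np.array([phases[i] for i in range(system.n_modules)])
        score = (circ_dist(templates, vec[None, :]) ** 2).sum(axis=1)
        best = score.min()
        close = np.flatnonzero(score <= best + ambiguity_tol)
        pick = int(close[np.argmin(np.abs(bins[close]))])
        out[gid] = PhaseDecodeResult(
            displacement=float(bins[pick]),
            score=float(score[pick]),
            ambiguous=close.size > 1,
        )
    return out


def decode_vector_2d(
    system: GridSystem,
    code_a: PhaseCode,
    code_b: PhaseCode,
    resolution: float | None = None,
) -> TranslationVector:
    """Per-axis phase-template decode on both principal axes."""
    return PhaseVectorCellModel(system, resolution=resolution).decode(code_a, code_b)


class PhaseVectorCellModel:
    """Prebuilt displacement templates on both axes."""

    name = "vector_phase"

    def __init__(self, system: GridSystem, resolution: float | None = None):
        if not system.shared_axes:
            raise ValueError("phase vector-cell decoding requires shared axes")
        self.system = system
        self.resolution = {}
        self._templates = {}
        for axis in (0, 1):
            res = resolution if resolution is not None else default_resolution(
                system, axis
            )
            self.resolution[axis] = res
            self._templates[axis] = displacement_templates(
                system, axis=axis, resolution=res
            )

    def decode_axis(self, code_a: PhaseCode, code_b: PhaseCode, axis: int) -> float:
        bins, templates = self._templates[axis]
        dp = phase_difference(code_a, code_b)
        vec = wrap_signed(dp.dphases[:, axis])
        score = (circ_dist(templates, vec[None, :]) ** 2).sum(axis=1)
        best = score.min()
        close = np.flatnonzero(score <= best + 1e-9)
        return float(bins[int(close[np.argmin(np.abs(bins[close]))])])

    def decode(self, code_a: PhaseCode, code_b: PhaseCode) -> TranslationVector:
        d1 = self.decode_axis(code_a, code_b, 0)
        d2 = self.decode_axis(code_a, code_b, 1)
        return TranslationVector(d1, d2, basis=self.system.basis)

    def axis_error_bound(self, axis: int) -> float:
        """A-priori per-axis decode error: half a displacement bin."""
        return self.resolution[axis] / 2.0
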