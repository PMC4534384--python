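"""The distance-cell decoder network.

An array of distance cells tiles one principal axis: each cell prefers a
unique location in [0, C) (C = system capacity) and receives input from
the phase-binned grid populations of every module, with synaptic weights
proportional to each grid cell's mean firing rate at the preferred
location. Winner-take-all competition leaves only the best-matching
distance cell active, so the array decodes the absolute (modulo-C)
position encoded by a phase code along that axis.

Two arrays per axis — one fed by the current-location code, one by the
goal code — project to a "move up" and a "move down" readout neuron with
weights that grow linearly in opposite directions along the axis. The
readout rate difference is affine in (goal − current) and is inverted to
a signed displacement; two non-collinear axes give the 2D translation
vector. In 2D, each distance cell pools all grid cells of a module that
share a common phase on its axis, which is exactly the phase-binned 1D
marginal used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gridcode import (
    GridSystem,
    PhaseCode,
    TranslationVector,
    axis_bin_phases,
    axis_population_rates,
)
from .algsolve import system_period


@dataclass(frozen=True)
class DistanceCellArray:
    """One axis-aligned array of location-tuned distance cells."""

    axis: int
    role: str  # "current" or "goal"
    preferred_locations: np.ndarray  # (N,) cm, spanning [0, C)
    weights: np.ndarray  # (N, B) grid→distance weights, rows max-normalized
    module_of_bin: np.ndarray  # (B,) module index of each grid input bin
    capacity: float

    @property
    def n_cells(self) -> int:
        return self.preferred_locations.size


@dataclass(frozen=True)
class ReadoutPair:
    """'Move up'/'move down' readout of a current/goal array pair.

    Weight rows: index 0 = from the current array, 1 = from the goal array;
    the two rows have strictly monotone, opposite slopes along the axis.
    """

    up_rate: float
    down_rate: float
    up_weights: np.ndarray  # (2, N)
    down_weights: np.ndarray  # (2, N)


@dataclass(frozen=True)
class WTAResult:
    winner: int | None
    preferred_location: float
    rate: float
    ok: bool


def default_resolution(system: GridSystem, axis: int = 0) -> float:
    """Array resolution δ: a quarter of the smallest effective scale."""
    return float(system.axis_scales(axis).min()) / 4.0


def build_weights(
    system: GridSystem,
    axis: int = 0,
    resolution: float | None = None,
    role: str = "current",
) -> DistanceCellArray:
    """Construct a distance-cell array for one axis.

    One cell per preferred location ℓ ∈ {0, δ, …, C−δ}; the weight from
    phase bin k of module i equals that bin's cosine-tuned rate at ℓ.
    ``resolution`` must divide the capacity C.
    """
    C = system_period(system, axis=axis)
    if not math.isfinite(C):
        raise ValueError(
            "system capacity is infinite; configure rationally related scales"
        )
    if resolution is None:
        resolution = default_resolution(system, axis)
    n_cells = C / resolution
    if abs(n_cells - round(n_cells)) > 1e-9:
        raise ValueError(f"resolution {resolution} does not divide capacity {C}")
    n_cells = round(n_cells)
    locs = np.arange(n_cells) * resolution
    scales = system.axis_scales(axis)
    cols = []
    module_of_bin = []
    for i, mod in enumerate(system.modules):
        m = mod.cells_per_axis
        phases_at_loc = 2.0 * math.pi * locs[:, None] / scales[i]
        w = 0.5 * (1.0 + np.cos(phases_at_loc - axis_bin_phases(m)[None, :]))
        cols.append(w)
        module_of_bin.extend([i] * m)
    W = np.hstack(cols)
    W = W / W.max(axis=1, keepdims=True)
    return DistanceCellArray(
        axis=axis,
        role=role,
        preferred_locations=locs,
        weights=W,
        module_of_bin=np.asarray(module_of_bin),
        capacity=C,
    )


def grid_input_rates(system: GridSystem, code: PhaseCode, axis: int) -> np.ndarray:
    """Concatenated phase-binned population rates of all modules on one axis."""
    return np.concatenate(
        [
            axis_population_rates(code.phases[i, axis], mod.cells_per_axis)
            for i, mod in enumerate(system.modules)
        ]
    )


def activate_wta(
    arr: DistanceCellArray, system: GridSystem, code: PhaseCode
) -> WTAResult:
    """Winner-take-all activation of the array by a phase code.

    Net input = weights · grid rates; the argmax cell survives, all others
    are silenced. Ties break to the smallest preferred location.
    """
    if code.n_modules != system.n_modules:
        raise ValueError("code/system module count mismatch")
    drive = arr.weights @ grid_input_rates(system, code, arr.axis)
    if not np.any(drive > 0):
        return WTAResult(winner=None, preferred_location=math.nan, rate=0.0, ok=False)
    w = int(np.argmax(drive))  # argmax returns the first (smallest-ℓ) maximum
    return WTAResult(
        winner=w,
        preferred_location=float(arr.preferred_locations[w]),
        rate=float(drive[w]),
        ok=True,
    )


def readout_rates(
    current: DistanceCellArray,
    goal: DistanceCellArray,
    system: GridSystem,
    code_a: PhaseCode,
    code_b: PhaseCode,
) -> ReadoutPair:
    """Rates of the up/down readout pair for a current/goal code pair.

    The winning distance cell of each array contributes its readout weight
    (winner activation normalized to 1). Up-weights increase with location
    for the goal array and decrease for the current array; down-weights
    mirror this, so up − down is affine in (goal − current).
    """
    if current.axis != goal.axis:
        raise ValueError("arrays must share an axis")
    C = current.capacity
    locs_c = current.preferred_locations
    locs_g = goal.preferred_locations
    up_w = np.vstack([(C - locs_c) / C, locs_g / C])
    down_w = np.vstack([locs_c / C, (C - locs_g) / C])
    wa = activate_wta(current, system, code_a)
    wb = activate_wta(goal, system, code_b)
    if not (wa.ok and wb.ok):
        raise ValueError("winner-take-all produced no winner")
    up = float(up_w[0, wa.winner] + up_w[1, wb.winner])
    down = float(down_w[0, wa.winner] + down_w[1, wb.winner])
    return ReadoutPair(up_rate=up, down_rate=down, up_weights=up_w, down_weights=down_w)


def readout_displacement(
    current: DistanceCellArray,
    goal: DistanceCellArray,
    system: GridSystem,
    code_a: PhaseCode,
    code_b: PhaseCode,
) -> float:
    """Signed displacement along the axis from the readout-rate difference.

    (up − down)·C/2 equals ℓ_goal − ℓ_current exactly for the constructed
    weights; the result is wrapped to [−C/2, C/2). Antisymmetric under
    swapping the two codes.
    """
    pair = readout_rates(current, goal, system, code_a, code_b)
    C = current.capacity
    d = (pair.up_rate - pair.down_rate) * C / 2.0
    return float(np.mod(d + C / 2.0, C) - C / 2.0)


def decode_vector_2d(
    system: GridSystem,
    code_a: PhaseCode,
    code_b: PhaseCode,
    resolution: float | None = None,
) -> TranslationVector:
    """Run the per-axis readout on both principal axes and assemble."""
    return DistanceCellModel(system, resolution=resolution).decode(code_a, code_b)


class DistanceCellModel:
    """Prebuilt current/goal arrays on both axes, reusable across decodes."""

    name = "distance"

    def __init__(self, system: GridSystem, resolution: float | None = None):
        if not system.shared_axes:
            raise ValueError("distance-cell 2D decoding requires shared axes")
        self.system = system
        self.arrays = {}
        self.resolution = {}
        for axis in (0, 1):
            res = resolution if resolution is not None else default_resolution(
                system, axis
            )
            self.resolution[axis] = res
            self.arrays[axis] = (
                build_weights(system, axis=axis, resolution=res, role="current"),
                build_weights(system, axis=axis, resolution=res, role="goal"),
            )

    def decode_axis(self, code_a: PhaseCode, code_b: PhaseCode, axis: int) -> float:
        cur, goal = self.arrays[axis]
        return readout_displacement(cur, goal, self.system, code_a, code_b)

    def decode(self, code_a: PhaseCode, code_b: PhaseCode) -> TranslationVector:
        d1 = self.decode_axis(code_a, code_b, 0)
        d2 = self.decode_axis(code_a, code_b, 1)
        return TranslationVector(d1, d2, basis=self.system.basis)

    def axis_error_bound(self, axis: int) -> float:
        """A-priori per-axis decode error: two δ-grid location quantizations."""
        return self.resolution[axis]
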