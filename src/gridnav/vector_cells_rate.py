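"""The rate-coded vector-cell decoder network.

Instead of decoding two absolute locations, a vector cell encodes one
displacement d along an axis and receives input — through multiplicative
synapses — from every pair of grid cells (current-coding, goal-coding)
within each module whose unwrapped phase difference corresponds to d,
i.e. d = (Δp/2π + n)·s for some integer n. When the current and goal
populations fire together, winner-take-all competition leaves only the
vector cell whose displacement is consistent across all modules. The
readout is translation invariant: it depends only on the phase
differences, never on the locations themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gridcode import (
    GridSystem,
    PhaseCode,
    TranslationVector,
    axis_population_rates,
)
from .algsolve import system_period


@dataclass(frozen=True)
class VectorCellArray:
    """One axis-aligned array of displacement-tuned vector cells.

    ``goal_bin`` gives, per module, the goal-population phase bin paired
    with each current-population bin for each vector cell: shape
    (n_cells, m_i); pair (k, goal_bin[c, k]) feeds vector cell c.
    """

    axis: int
    encoded_displacements: np.ndarray  # (D,) cm in [−C/2, C/2)
    goal_bin: tuple[np.ndarray, ...]  # per module, (D, m_i) int
    capacity: float

    @property
    def n_cells(self) -> int:
        return self.encoded_displacements.size

    def pairs(self, cell: int, module: int) -> list[tuple[int, int]]:
        """(current bin, goal bin) index pairs feeding one vector cell."""
        gb = self.goal_bin[module][cell]
        return [(k, int(gb[k])) for k in range(gb.size)]


@dataclass(frozen=True)
class VectorWTAResult:
    winner: int | None
    displacement: float
    rate: float
    ok: bool


def default_resolution(system: GridSystem, axis: int = 0) -> float:
    """Vector-cell resolution δ_v: a quarter of the smallest effective scale."""
    return float(system.axis_scales(axis).min()) / 4.0


def build_pair_table(
    system: GridSystem, axis: int = 0, resolution: float | None = None
) -> VectorCellArray:
    """Enumerate grid-cell pairs for every displacement bin and module.

    For vector cell at displacement d and module i, current bin k pairs
    with the goal bin nearest to phase φ_k + 2πd/s_i (wrapped) — exactly
    one goal bin per current bin, so each module contributes m_i pairs to
    every vector cell.
    """
    C = system_period(system, axis=axis)
    if not math.isfinite(C):
        raise ValueError("system capacity is infinite")
    if resolution is None:
        resolution = default_resolution(system, axis)
    scales = system.axis_scales(axis)
    finest_bin_cm = min(
        s / mod.cells_per_axis for s, mod in zip(scales, system.modules, strict=True)
    )
    if resolution < finest_bin_cm - 1e-12:
        raise ValueError(
            f"resolution {resolution} cm is finer than the smallest module's "
            f"phase-bin spacing ({finest_bin_cm} cm)"
        )
    n_cells = round(C / resolution)
    disps = -C / 2.0 + np.arange(n_cells) * resolution
    goal_bin = []
    for i, mod in enumerate(system.modules):
        m = mod.cells_per_axis
        shift = np.round(disps * m / scales[i]).astype(int) % m
        k = np.arange(m)
        goal_bin.append((k[None, :] + shift[:, None]) % m)
    return VectorCellArray(
        axis=axis,
        encoded_displacements=disps,
        goal_bin=tuple(goal_bin),
        capacity=C,
    )


def drive(
    arr: VectorCellArray, rates_a: list[np.ndarray], rates_b: list[np.ndarray]
) -> np.ndarray:
    """Multiplicative drive to every vector cell.

    rates_a/rates_b are per-module phase-binned population rate vectors of
    the simultaneously active current and goal populations. Each vector
    cell sums the products of its paired pre-synaptic rates, so silencing
    either population silences the whole array (conjunctive gating).
    """
    total = np.zeros(arr.n_cells)
    for i, gb in enumerate(arr.goal_bin):
        m = gb.shape[1]
        # circular cross-correlation of the two population vectors
        idx = (np.arange(m)[:, None] + np.arange(m)[None, :]) % m
        xcorr = rates_b[i][idx] @ rates_a[i]  # xcorr[s] = Σ_k a[k]·b[k+s]
        total += xcorr[gb[:, 0]]
    return total


def activate(
    arr: VectorCellArray,
    system: GridSystem,
    code_a: PhaseCode,
    code_b: PhaseCode,
) -> VectorWTAResult:
    """Winner-take-all over the vector-cell array; ties go to smallest |d|."""
    rates_a = [
        axis_population_rates(code_a.phases[i, arr.axis], mod.cells_per_axis)
        for i, mod in enumerate(system.modules)
    ]
    rates_b = [
        axis_population_rates(code_b.phases[i, arr.axis], mod.cells_per_axis)
        for i, mod in enumerate(system.modules)
    ]
    inp = drive(arr, rates_a, rates_b)
    if not np.any(inp > 0):
        return VectorWTAResult(winner=None, displacement=math.nan, rate=0.0, ok=False)
    top = np.flatnonzero(inp >= inp.max() - 1e-12)
    w = int(top[np.argmin(np.abs(arr.encoded_displacements[top]))])
    return VectorWTAResult(
        winner=w,
        displacement=float(arr.encoded_displacements[w]),
        rate=float(inp[w]),
        ok=True,
    )


def decode_vector_2d(
    system: GridSystem,
    code_a: PhaseCode,
    code_b: PhaseCode,
    resolution: float | None = None,
) -> TranslationVector:
    """Per-axis vector-cell decode on both principal axes."""
    return RateVectorCellModel(system, resolution=resolution).decode(code_a, code_b)


class RateVectorCellModel:
    """Prebuilt pair tables on both axes, reusable across decodes.

    ``variable_resolution`` coarsens the displacement bins with |d|
    (δ_v(d) = δ_0 · max(1, |d|/s_1)), trading far-range precision for
    fewer cells; off by default. With it on, re-decoding as the goal is
    approached recovers full precision near the goal.
    """

    name = "vector_rate"

    def __init__(
        self,
        system: GridSystem,
        resolution: float | None = None,
        variable_resolution: bool = False,
    ):
        if not system.shared_axes:
            raise ValueError("rate vector-cell decoding requires shared axes")
        self.system = system
        self.arrays = {}
        self.resolution = {}
        for axis in (0, 1):
            res = resolution if resolution is not None else default_resolution(
                system, axis
            )
            self.resolution[axis] = res
            arr = build_pair_table(system, axis=axis, resolution=res)
            if variable_resolution:
                arr = _coarsen(arr, system, res)
            self.arrays[axis] = arr

    def decode_axis(self, code_a: PhaseCode, code_b: PhaseCode, axis: int) -> float:
        r = activate(self.arrays[axis], self.system, code_a, code_b)
        if not r.ok:
            raise ValueError("vector-cell array received no drive")
        return r.displacement

    def decode(self, code_a: PhaseCode, code_b: PhaseCode) -> TranslationVector:
        d1 = self.decode_axis(code_a, code_b, 0)
        d2 = self.decode_axis(code_a, code_b, 1)
        return TranslationVector(d1, d2, basis=self.system.basis)

    def axis_error_bound(self, axis: int) -> float:
        """A-priori per-axis decode error.

        Two quantizers act in series: the displacement grid (half a bin)
        and the snapping of each pair's phase shift to the module's phase
        bins (up to s_i/(2·m_i) cm in the coarsest-binned module).
        """
        snap = max(
            s / (2.0 * mod.cells_per_axis)
            for s, mod in zip(
                self.system.axis_scales(axis), self.system.modules, strict=True
            )
        )
        return self.resolution[axis] / 2.0 + snap


def _coarsen(
    arr: VectorCellArray, system: GridSystem, res0: float
) -> VectorCellArray:
    """Thin the displacement bins so spacing grows with |d| (δ_v(d)).

    Each surviving cell keeps its exact residue pair table; far-range
    displacements falling between coarse bins are therefore only decoded
    approximately, and are meant to be refined by re-decoding as the goal
    is approached (the spacing near d = 0 stays at full resolution).
    """
    s1 = float(system.scales[0])
    keep: list[int] = []
    d = arr.encoded_displacements
    for j in np.argsort(np.abs(d), kind="stable"):
        step = res0 * max(1.0, abs(d[j]) / s1)
        if all(abs(d[j] - d[k]) >= step - 1e-9 for k in keep):
            keep.append(j)
    keep = sorted(keep)
    return VectorCellArray(
        axis=arr.axis,
        encoded_displacements=d[keep],
        goal_bin=tuple(gb[keep] for gb in arr.goal_bin),
        capacity=arr.capacity,
    )
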