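"""Grid-cell phase coding of location.

Grid cells in medial entorhinal cortex fire on a hexagonal lattice of
locations. Cells are organised into modules: populations that share a
spatial scale and orientation but differ in spatial phase offset. Within
a module, the animal's position is captured — modulo one lattice tile —
by a pair of phases ``(p_x, p_y)`` in ``[0, 2π)`` along two non-collinear
principal axes of the lattice (the "twisted torus" topology). Across M
modules of different scales the set of phases forms a residue-number-like
code whose unambiguous range approaches the least common multiple of the
module scales.

This module defines the configuration types (:class:`GridModule`,
:class:`GridSystem`) and the forward model: mapping Cartesian locations to
phase codes (:func:`encode_location`), differencing codes
(:func:`phase_difference`), and generating hexagonal firing-rate maps and
population activity for the network decoders.

Conventions
-----------
* Phases are wrapped to the half-open interval ``[0, 2π)``.
* All modules share a phase origin at the world origin.
* The two principal axes are separated by 60° by default, so the grid
  scale is the same along each; ellipticity rescales axis 2 only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * math.pi

#: Default tolerance (rad) for phase equality checks.
PHASE_TOL = 1e-9


class ConfigurationError(ValueError):
    """Raised for invalid grid-system configurations (e.g. collinear axes)."""


def wrap_phase(x):
    """Wrap angle(s) to ``[0, 2π)``.

    Guaranteed non-negative and strictly below 2π (``np.mod`` of a tiny
    negative number can round to exactly 2π; that case is mapped to 0).
    """
    p = np.mod(np.asarray(x, dtype=float), TWO_PI)
    p = np.where(p >= TWO_PI, 0.0, p)
    return float(p) if p.ndim == 0 else p


def wrap_signed(x):
    """Wrap angle(s) to ``(−π, π]``."""
    p = np.mod(np.asarray(x, dtype=float), TWO_PI)
    p = np.where(p >= TWO_PI, 0.0, p)
    p = np.where(p > math.pi, p - TWO_PI, p)
    return float(p) if p.ndim == 0 else p


def circ_dist(a, b):
    """Absolute circular distance between angles, in ``[0, π]``."""
    return np.abs(wrap_signed(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


@dataclass(frozen=True)
class GridModule:
    """One grid module: a population of cells sharing scale and orientation.

    Parameters
    ----------
    scale : float
        Grid scale ``s_i`` in cm (distance between adjacent firing fields
        along a principal axis).
    orientation : float
        Angle (rad) of the first principal axis in the world frame.
    axis_separation : float
        Angle (rad) between the two principal axes; 60° by default so the
        scale is equal along both axes of the hexagonal lattice.
    ellipticity : float
        Scale multiplier along axis 2 (1.0 = circularly symmetric grid).
    cells_per_axis : int
        Number of phase bins per axis, ``m_i``; sets the phase resolution
        of the network models but not the information content of the code.
    """

    scale: float
    orientation: float = 0.0
    axis_separation: float = math.pi / 3
    ellipticity: float = 1.0
    cells_per_axis: int = 32

    def __post_init__(self):
        if not (self.scale > 0):
            raise ConfigurationError(f"scale must be > 0, got {self.scale}")
        if not (0 < self.axis_separation < math.pi):
            raise ConfigurationError(
                f"axis_separation must lie in (0, π), got {self.axis_separation}"
            )
        if not (self.ellipticity > 0):
            raise ConfigurationError(f"ellipticity must be > 0, got {self.ellipticity}")
        if self.cells_per_axis < 2:
            raise ConfigurationError(
                f"cells_per_axis must be ≥ 2, got {self.cells_per_axis}"
            )

    @property
    def axis_scales(self) -> tuple[float, float]:
        """Effective scale (cm) along each principal axis."""
        return (self.scale, self.scale * self.ellipticity)

    @property
    def basis(self) -> np.ndarray:
        """2×2 matrix whose columns are the unit vectors of the two axes."""
        t1 = self.orientation
        t2 = self.orientation + self.axis_separation
        return np.array([[math.cos(t1), math.cos(t2)], [math.sin(t1), math.sin(t2)]])

    @property
    def lattice_basis(self) -> np.ndarray:
        """2×2 matrix whose columns are the lattice (tile) vectors in cm."""
        return self.basis * np.asarray(self.axis_scales)


@dataclass(frozen=True)
class GridSystem:
    """An ordered collection of grid modules, largest scale first.

    ``shared_axes`` asserts that all modules have identical orientation and
    axis separation, in which case the 2D decoding problem separates into
    two independent 1D problems along the common axes.
    """

    modules: tuple[GridModule, ...]
    shared_axes: bool = True

    def __post_init__(self):
        mods = tuple(self.modules)
        object.__setattr__(self, "modules", mods)
        if len(mods) < 1:
            raise ConfigurationError("GridSystem needs at least one module")
        scales = [m.scale for m in mods]
        if any(a < b for a, b in zip(scales, scales[1:], strict=False)):
            raise ConfigurationError(
                f"module scales must be non-increasing, got {scales}"
            )
        if self.shared_axes:
            ref = mods[0]
            for m in mods[1:]:
                if (
                    abs(m.orientation - ref.orientation) > 1e-12
                    or abs(m.axis_separation - ref.axis_separation) > 1e-12
                ):
                    raise ConfigurationError(
                        "shared_axes=True but module orientations/separations differ"
                    )

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def scales(self) -> np.ndarray:
        return np.array([m.scale for m in self.modules])

    def axis_scales(self, axis: int) -> np.ndarray:
        """Effective scale of every module along the given axis (0 or 1)."""
        return np.array([m.axis_scales[axis] for m in self.modules])

    @property
    def basis(self) -> np.ndarray:
        """Shared axis basis (columns = unit axis vectors) of module 0."""
        return self.modules[0].basis


def from_scales(scales, **module_kwargs) -> GridSystem:
    """Convenience constructor: one module per scale, shared axes."""
    mods = tuple(GridModule(scale=float(s), **module_kwargs) for s in scales)
    return GridSystem(modules=mods)


@dataclass(frozen=True)
class Location:
    """A Cartesian location in the world frame, in cm (1D problems use y=0)."""

    x: float
    y: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Location must be finite, got ({self.x}, {self.y})")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class PhaseCode:
    """Per-module pairs of spatial phases ``(p_x, p_y)`` in ``[0, 2π)``."""

    phases: np.ndarray  # shape (M, 2)

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.phases, dtype=float))
        if p.shape[1] != 2:
            raise ValueError(f"phases must have shape (M, 2), got {p.shape}")
        if np.any(p < 0) or np.any(p >= TWO_PI):
            raise ValueError("phases must lie in [0, 2π)")
        object.__setattr__(self, "phases", p)

    @property
    def n_modules(self) -> int:
        return self.phases.shape[0]

    def axis(self, axis: int) -> np.ndarray:
        """Phases of every module along one axis."""
        return self.phases[:, axis]


@dataclass(frozen=True)
class PhaseDiff:
    """Per-module pairs of wrapped phase differences ``(Δp_x, Δp_y)``.

    Depends only on the displacement between the two encoded locations,
    never on the locations themselves (translation invariance).
    """

    dphases: np.ndarray  # shape (M, 2)

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.dphases, dtype=float))
        if p.shape[1] != 2:
            raise ValueError(f"dphases must have shape (M, 2), got {p.shape}")
        if np.any(p < 0) or np.any(p >= TWO_PI):
            raise ValueError("dphases must lie in [0, 2π)")
        object.__setattr__(self, "dphases", p)

    @property
    def n_modules(self) -> int:
        return self.dphases.shape[0]

    def axis(self, axis: int) -> np.ndarray:
        return self.dphases[:, axis]


@dataclass(frozen=True)
class TranslationVector:
    """A decoded displacement, stored as components along the grid axes.

    ``cartesian`` is the exact linear image of ``(d_axis1, d_axis2)`` under
    the (generally non-orthogonal) axis unit vectors.
    """

    d_axis1: float
    d_axis2: float
    basis: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self):
        object.__setattr__(self, "basis", np.asarray(self.basis, dtype=float))

    @property
    def axis_components(self) -> np.ndarray:
        return np.array([self.d_axis1, self.d_axis2])

    @property
    def cartesian(self) -> np.ndarray:
        return self.basis @ self.axis_components

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.cartesian))


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def project_onto_axes(loc: Location, sys_or_module) -> tuple[float, float]:
    """Coordinates (u, v) of ``loc`` in the grid-axis basis: loc = u·x̂ + v·ŷ.

    Accepts a :class:`GridSystem` (shared axes; module 0's basis is used)
    or a single :class:`GridModule`.
    """
    if isinstance(sys_or_module, GridSystem):
        if not sys_or_module.shared_axes:
            raise ConfigurationError(
                "project_onto_axes on a GridSystem requires shared_axes; "
                "project per module instead"
            )
        basis = sys_or_module.basis
    else:
        basis = sys_or_module.basis
    det = basis[0, 0] * basis[1, 1] - basis[0, 1] * basis[1, 0]
    if abs(det) < 1e-12:
        raise ConfigurationError("grid axes are collinear")
    uv = np.linalg.solve(basis, loc.xy)
    return float(uv[0]), float(uv[1])


def encode_location(loc: Location, system: GridSystem) -> PhaseCode:
    """Encode a location as the set of per-module, per-axis phases.

    For module i and axis j with effective scale s:
    ``p = 2π · ((coord_j mod s) / s)``, wrapped to ``[0, 2π)``. The code is
    periodic: moving by one scale along an axis leaves that module's phase
    unchanged.
    """
    phases = np.empty((system.n_modules, 2))
    for i, mod in enumerate(system.modules):
        u, v = project_onto_axes(loc, mod)
        s1, s2 = mod.axis_scales
        phases[i, 0] = wrap_phase(TWO_PI * (u / s1))
        phases[i, 1] = wrap_phase(TWO_PI * (v / s2))
    return PhaseCode(phases)


def phase_difference(code_a: PhaseCode, code_b: PhaseCode) -> PhaseDiff:
    """Wrapped phase difference ``p(b) − p(a)`` per module and axis."""
    if code_a.n_modules != code_b.n_modules:
        raise ValueError(
            f"module count mismatch: {code_a.n_modules} vs {code_b.n_modules}"
        )
    return PhaseDiff(wrap_phase(code_b.phases - code_a.phases))


# ---------------------------------------------------------------------------
# Firing-rate model (three-cosine hexagonal pattern)
# ---------------------------------------------------------------------------

def _reciprocal_vectors(module: GridModule) -> np.ndarray:
    """Columns b1, b2 of the reciprocal lattice: B^T A = 2π I."""
    A = module.lattice_basis
    return TWO_PI * np.linalg.inv(A).T


def rate_map(cell_phase_offset, loc: Location, module: GridModule) -> float:
    """Normalized firing rate of one grid cell at a location, in [0, 1].

    Three-cosine hexagonal model: the sum of cosines over the three grid
    wave vectors (the two reciprocal lattice vectors and their sum), with
    the pattern anchored at the cell's phase offset, affinely rescaled from
    [−1.5, 3] to [0, 1]. The rate is exactly 1 at the cell's firing-field
    lattice points and exactly 0 at the centroids of adjacent field
    triplets.
    """
    phi = np.asarray(cell_phase_offset, dtype=float)
    B = _reciprocal_vectors(module)
    t = B.T @ loc.xy  # unwrapped phases along each axis
    a1 = t[0] - phi[0]
    a2 = t[1] - phi[1]
    g = math.cos(a1) + math.cos(a2) + math.cos(a1 + a2)
    return (g + 1.5) / 4.5


def offset_grid(module: GridModule) -> np.ndarray:
    """Phase offsets (m², 2) of the cells on the module's phase sheet.

    Cells are placed on a uniform ``m × m`` grid over the unit tile,
    row-major in (axis-1 offset, axis-2 offset).
    """
    m = module.cells_per_axis
    step = TWO_PI / m
    p1, p2 = np.meshgrid(np.arange(m) * step, np.arange(m) * step, indexing="ij")
    return np.column_stack([p1.ravel(), p2.ravel()])


def population_activity(loc: Location, module: GridModule) -> np.ndarray:
    """Rates of all m² cells of a module at a location (single bump).

    The argmax cell's phase offset agrees with :func:`encode_location` for
    that module to within one phase-grid step; the summed rate is invariant
    under translation of the location (the bump moves, its mass does not).
    """
    offsets = offset_grid(module)
    B = _reciprocal_vectors(module)
    t = B.T @ loc.xy
    a1 = t[0] - offsets[:, 0]
    a2 = t[1] - offsets[:, 1]
    g = np.cos(a1) + np.cos(a2) + np.cos(a1 + a2)
    return (g + 1.5) / 4.5


# ---------------------------------------------------------------------------
# 1D phase-binned population rates (shared plumbing for network decoders)
# ---------------------------------------------------------------------------

def axis_bin_phases(n_bins: int) -> np.ndarray:
    """Preferred phases of the n uniform phase bins on one axis."""
    return TWO_PI * np.arange(n_bins) / n_bins


def axis_population_rates(phase: float, n_bins: int) -> np.ndarray:
    """Cosine-tuned rates of the phase-binned population on one axis.

    Bin k (preferred phase 2πk/m) fires at ``(1 + cos(p − φ_k)) / 2``; this
    is the 1D marginal of the hexagonal rate map onto a principal axis,
    normalized to [0, 1].
    """
    return 0.5 * (1.0 + np.cos(phase - axis_bin_phases(n_bins)))
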