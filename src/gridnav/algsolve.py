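"""Algorithmic decoder for modular grid-phase codes.

The phase of one module is periodic, so a wrapped phase difference Δp_i
stands for the infinite family of unwrapped phases Δp_i + 2πn_i, i.e. the
displacements d = s_i (Δp_i/2π + n_i). Across modules there is a single
coherent integer set {n_i} (within the system's capacity) for which the
unwrapped phases, plotted against inverse grid scale 1/s_i, fall on a
straight line through the origin with gradient 2πd — the Fourier-shift
view of the code. Decoding therefore amounts to: enumerate candidate
integer sets, fit the line (1D) or plane (2D) through the origin, and keep
the candidate with the smallest residual whose displacement lies within
the unambiguous range.

Candidate enumeration is anchored on the largest module: each hypothesis
d_k = (Δp_1/2π + n_1)·s_1 for n_1 in range determines the remaining wrap
counts by rounding, which is O(C/s_1 · M) rather than a product over
modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .gridcode import (
    TWO_PI,
    GridSystem,
    PhaseDiff,
    TranslationVector,
    circ_dist,
    wrap_phase,
)

#: Default rms phase residual (rad) below which a noise-free decode counts
#: as successful. Configurable for noisy input.
RESIDUAL_THRESHOLD = 1e-6

_RATIONAL_MAX_DEN = 10**6


@dataclass(frozen=True)
class UnwrapCandidate:
    """One coherent integer assignment {n_i} and its unwrapped phases."""

    n: tuple[int, ...]
    unwrapped: np.ndarray
    d_hint: float  # displacement hypothesis that generated the candidate


@dataclass(frozen=True)
class DecodeReport:
    """Decoder output plus diagnostics."""

    vector: TranslationVector
    residual: float  # rms phase misfit, rad
    candidate: UnwrapCandidate | None
    success: bool


def _rational_lcm(scales) -> float | None:
    """Exact LCM of scales if they are rationally related, else None."""
    fracs = []
    for s in scales:
        f = Fraction(float(s)).limit_denominator(_RATIONAL_MAX_DEN)
        if abs(float(f) - float(s)) > 1e-9 * float(s):
            return None
        fracs.append(f)
    den = math.lcm(*(f.denominator for f in fracs))
    nums = [f.numerator * (den // f.denominator) for f in fracs]
    return math.lcm(*nums) / den


def system_period(
    system: GridSystem,
    axis: int = 0,
    resolution: float | None = None,
    method: str = "auto",
    max_range: float = 1e6,
    phase_tol: float = 1e-6,
) -> float:
    """Capacity C of the system along one axis, in cm.

    The smallest displacement C > 0 after which every module's phase
    returns to its starting value, bounding the range over which the
    multi-module code is unambiguous (the LCM of the module scales when
    those are rationally related).

    ``method`` is "lcm" (rational reduction; error if scales are not
    rationally related), "scan" (numeric phase-coincidence scan at
    ``resolution``), or "auto" (lcm with scan fallback). A scan exceeding
    ``max_range`` returns ``math.inf`` (effectively aperiodic).
    """
    scales = system.axis_scales(axis)
    if method not in ("auto", "lcm", "scan"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("auto", "lcm"):
        C = _rational_lcm(scales)
        if C is not None:
            # A period beyond max_range is indistinguishable from aperiodic
            # for any finite workspace (and typically a rationalization
            # artifact of irrational scale ratios).
            return C if C <= max_range else math.inf
        if method == "lcm":
            raise ValueError("scales are not rationally related; use a scan")
    if resolution is None:
        resolution = float(scales.min()) / 100.0
    if not resolution > 0:
        raise ValueError("resolution must be > 0")
    # Coincidence scan: first displacement where all phases rewrap to 0.
    # Tolerance is half a scan step expressed as phase in the smallest module.
    tol = max(phase_tol, math.pi * resolution / float(scales.min()))
    n_steps = int(max_range / resolution)
    k = np.arange(1, n_steps + 1)
    err = np.zeros(n_steps)
    for s in scales:
        err = np.maximum(err, circ_dist(TWO_PI * k * resolution / s, 0.0))
    hits = np.flatnonzero(err <= tol)
    if hits.size == 0:
        return math.inf
    return float(k[hits[0]] * resolution)


def _as_axis_dp(dp, axis: int) -> np.ndarray:
    if isinstance(dp, PhaseDiff):
        return dp.axis(axis)
    return wrap_phase(np.asarray(dp, dtype=float))


def unwrap_candidates(dp, system: GridSystem, axis: int = 0) -> list[UnwrapCandidate]:
    """Enumerate coherent integer sets {n_i} for one axis of a phase diff.

    Anchored on module 1 (largest scale): every hypothesis
    d = (Δp_1/2π + n_1)·s_1 with d in [−C/2, C/2) fixes the other modules'
    wrap counts by rounding. Deduplicated on the integer tuple.
    """
    if system.n_modules < 1:
        raise ValueError("empty grid system")
    dpa = _as_axis_dp(dp, axis)
    scales = system.axis_scales(axis)
    C = system_period(system, axis=axis)
    if not math.isfinite(C):
        raise ValueError("system is effectively aperiodic; no finite candidate set")
    s1 = scales[0]
    f1 = dpa[0] / TWO_PI
    n_lo = math.ceil(-C / (2 * s1) - f1 - 1e-12)
    n_hi = math.floor((C / 2 - 1e-9) / s1 - f1)
    out: list[UnwrapCandidate] = []
    seen: set[tuple[int, ...]] = set()
    for n1 in range(n_lo, n_hi + 1):
        d = (f1 + n1) * s1
        n = np.round(d / scales - dpa / TWO_PI).astype(int)
        n[0] = n1
        key = tuple(int(v) for v in n)
        if key in seen:
            continue
        seen.add(key)
        out.append(UnwrapCandidate(n=key, unwrapped=dpa + TWO_PI * n, d_hint=d))
    return out


def _linefit_1d(
    dpa: np.ndarray,
    scales: np.ndarray,
    C: float,
    residual_threshold: float,
    system: GridSystem,
    axis: int,
) -> tuple[float, float, UnwrapCandidate | None, bool]:
    """Core 1D fit over candidates; returns (d, residual, candidate, success)."""
    x = 1.0 / scales
    best = None  # (residual, |d|, d, cand)
    for cand in unwrap_candidates(dpa, system, axis=axis):
        y = cand.unwrapped
        slope = float(x @ y) / float(x @ x)
        d = slope / TWO_PI
        if not (-C / 2 - 1e-9 <= d < C / 2):
            continue
        resid = float(np.sqrt(np.mean((y - slope * x) ** 2)))
        key = (resid, abs(d))
        if best is None or key < best[0]:
            best = (key, d, resid, cand)
    if best is None:
        return 0.0, math.inf, None, False
    _, d, resid, cand = best
    return d, resid, cand, resid <= residual_threshold


def decode_1d_linefit(
    dp,
    system: GridSystem,
    axis: int = 0,
    residual_threshold: float = RESIDUAL_THRESHOLD,
) -> DecodeReport:
    """Decode a 1D displacement from one axis of a phase difference.

    For each unwrap candidate, least-squares fit of unwrapped phase vs.
    inverse scale through the origin; slope/2π is the displacement. The
    winning candidate has minimal residual (ties to smaller |d|) and a
    displacement in [−C/2, C/2). Exact to numerical precision on
    noise-free input.
    """
    dpa = _as_axis_dp(dp, axis)
    scales = system.axis_scales(axis)
    C = system_period(system, axis=axis)
    d, resid, cand, ok = _linefit_1d(
        dpa, scales, C, residual_threshold, system, axis
    )
    comp = [0.0, 0.0]
    comp[axis] = d
    vec = TranslationVector(comp[0], comp[1], basis=system.basis)
    return DecodeReport(vector=vec, residual=resid, candidate=cand, success=ok)


def decode_2d_planefit(
    dp: PhaseDiff,
    system: GridSystem,
    residual_threshold: float = RESIDUAL_THRESHOLD,
) -> DecodeReport:
    """Decode a 2D displacement from a phase difference.

    With shared module axes the plane fit separates exactly into two
    independent line fits, one per principal axis. Otherwise a single
    plane through the origin is fitted to the family of points (wave
    vector, unwrapped phase) over all modules and axes, with candidate
    integer assignments anchored on the largest module.
    """
    if system.shared_axes:
        rx = decode_1d_linefit(dp, system, axis=0, residual_threshold=residual_threshold)
        ry = decode_1d_linefit(dp, system, axis=1, residual_threshold=residual_threshold)
        resid = math.hypot(rx.residual, ry.residual) / math.sqrt(2.0)
        cand = None
        if rx.candidate is not None and ry.candidate is not None:
            cand = UnwrapCandidate(
                n=rx.candidate.n + ry.candidate.n,
                unwrapped=np.concatenate(
                    [rx.candidate.unwrapped, ry.candidate.unwrapped]
                ),
                d_hint=math.nan,
            )
        vec = TranslationVector(
            rx.vector.d_axis1, ry.vector.d_axis2, basis=system.basis
        )
        return DecodeReport(
            vector=vec,
            residual=resid,
            candidate=cand,
            success=rx.success and ry.success,
        )
    return _decode_2d_general(dp, system, residual_threshold)


def _decode_2d_general(
    dp: PhaseDiff, system: GridSystem, residual_threshold: float
) -> DecodeReport:
    """General plane fit for modules with differing orientations/ellipticity.

    Each module/axis contributes one equation 2π g·d = Δp + 2πn, where g is
    the corresponding dual-basis (reciprocal-lattice / 2π) vector of the
    module's tile — the Fourier component sampled by that axis. Hypotheses
    for d come from the two axis equations of the largest module; the
    remaining wrap counts are snapped by rounding and the plane is refit by
    least squares over all 2M equations.
    """
    M = system.n_modules
    G = np.zeros((2 * M, 2))
    dpa = np.zeros(2 * M)
    for i, mod in enumerate(system.modules):
        Ainv = np.linalg.inv(mod.lattice_basis)  # rows = dual basis vectors
        G[2 * i] = Ainv[0]
        G[2 * i + 1] = Ainv[1]
        dpa[2 * i] = dp.dphases[i, 0]
        dpa[2 * i + 1] = dp.dphases[i, 1]
    # Range bound: period of the pooled effective scales (heuristic when
    # axes differ between modules; exact when they coincide).
    all_scales = np.concatenate([system.axis_scales(0), system.axis_scales(1)])
    C = _rational_lcm(all_scales)
    if C is None:
        C = float(all_scales.max()) * 50
    mod0 = system.modules[0]
    G0 = G[:2]
    n_max = math.ceil(C / (2 * min(mod0.axis_scales))) + 1
    best = None
    for n1 in range(-n_max, n_max + 1):
        for n2 in range(-n_max, n_max + 1):
            rhs = np.array([dpa[0] + TWO_PI * n1, dpa[1] + TWO_PI * n2]) / TWO_PI
            try:
                d_hyp = np.linalg.solve(G0, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.linalg.norm(d_hyp) > C / 2 * 1.001:
                continue
            n = np.round(G @ d_hyp - dpa / TWO_PI).astype(int)
            y = dpa + TWO_PI * n
            d_fit, *_ = np.linalg.lstsq(TWO_PI * G, y, rcond=None)
            resid = float(np.sqrt(np.mean((y - TWO_PI * G @ d_fit) ** 2)))
            key = (resid, float(np.linalg.norm(d_fit)))
            if best is None or key < best[0]:
                best = (key, d_fit, resid, tuple(int(v) for v in n))
    if best is None:
        vec = TranslationVector(0.0, 0.0, basis=system.basis)
        return DecodeReport(vector=vec, residual=math.inf, candidate=None, success=False)
    _, d_cart, resid, n = best
    uv = np.linalg.solve(system.basis, d_cart)
    cand = UnwrapCandidate(n=n, unwrapped=dpa + TWO_PI * np.asarray(n), d_hint=math.nan)
    vec = TranslationVector(float(uv[0]), float(uv[1]), basis=system.basis)
    return DecodeReport(
        vector=vec, residual=resid, candidate=cand,
        success=resid <= residual_threshold,
    )


def brute_force_oracle(
    dp: PhaseDiff, system: GridSystem, resolution: float
) -> TranslationVector:
    """Independent grid-scan decoder, for verification only.

    Scores every displacement on a grid covering [−C/2, C/2)² per axis by
    the summed squared circular distance between its predicted phase
    differences and the observed ones, and returns the minimizer. With
    shared axes the objective separates, so each axis is scanned
    independently (the minimiser over the full 2D grid is identical).
    """
    if not system.shared_axes:
        raise NotImplementedError("oracle requires shared axes")
    if resolution > float(system.axis_scales(0).min()) / 20 + 1e-12:
        raise ValueError("oracle resolution must be ≤ s_M/20")
    comps = []
    for axis in (0, 1):
        scales = system.axis_scales(axis)
        C = system_period(system, axis=axis)
        grid = np.arange(-C / 2, C / 2, resolution)
        score = np.zeros(grid.size)
        for i, s in enumerate(scales):
            pred = TWO_PI * grid / s
            score += circ_dist(pred, dp.dphases[i, axis]) ** 2
        comps.append(float(grid[int(np.argmin(score))]))
    return TranslationVector(comps[0], comps[1], basis=system.basis)
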