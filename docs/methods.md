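# Methods

## The code and the problem

A grid system is a set of M modules, ordered largest scale first
(s_1 ≥ … ≥ s_M, in cm). All modules share two principal axes, separated
by 60° by default so that the grid scale is equal along each (oblique,
non-orthogonal coordinates); per-module orientations and ellipticity
(axis-2 scale multiplier) are supported and handled by the general plane
fit. A location is encoded per module and axis as a wrapped spatial
phase

p = 2π · ((u mod s) / s) ∈ [0, 2π),

where u is the location's *oblique* axis coordinate (the component in
the dual basis of the lattice tile, not an orthogonal projection). All
modules share a phase origin at the world origin. Phase differences
between two codes are wrapped the same way and depend only on the
displacement between the locations.

The multi-module code is a residue number system: it determines a
displacement only modulo the system period C, the smallest displacement
returning every module phase to its start. For rationally related scales
C is their least common multiple (computed exactly via
`fractions.Fraction.limit_denominator(10⁶)`); a numeric coincidence scan
is provided as the discretized alternative, and a period beyond the
configured maximum range (default 10⁶ cm) is reported as effectively
aperiodic (C = ∞). Decoded displacements are reported in the symmetric
branch [−C/2, C/2) per axis. Errors against ground truth are always
circular (modulo C): a true displacement of +C/2 − ε decoded as
−C/2 + δ is a boundary wrap, not a failure.

## Algorithmic solver

A wrapped difference Δp_i represents the family Δp_i + 2πn_i; the
coherent integer set satisfies Δp_i + 2πn_i = 2πd·(1/s_i), a line
through the origin in (1/s_i, unwrapped phase). Candidates are anchored
on the largest module — each hypothesis d = (Δp_1/2π + n_1)·s_1 within
[−C/2, C/2) fixes the other n_i by rounding — giving O(C/s_1 · M)
candidates instead of a product over modules. Each candidate is scored
by the rms residual of the least-squares line (slope/2π = d); the
minimal-residual candidate wins, ties to smaller |d|. Noise-free input
decodes to machine precision; `success` requires rms residual ≤ 10⁻⁶ rad
(configurable for noisy input — there is no principled universal
threshold, so it is a parameter).

With shared axes the 2D problem separates exactly into two 1D fits.
Otherwise every module/axis contributes one equation 2π g·d = Δp + 2πn
with g the corresponding dual-basis (reciprocal-lattice/2π) vector;
hypotheses come from the largest module's two equations, remaining wrap
counts are snapped by rounding, and d is refit by least squares over all
2M equations. Modules are weighted equally in all fits.

The brute-force oracle scans displacements on a grid over [−C/2, C/2)
per axis (resolution ≤ s_M/20), scoring by summed squared circular
distance between predicted and observed phase differences. It exists
only as an independent check in tests.

## Network decoders

All four network models consume, per module and axis, a phase-binned
population rate vector with m_i bins (default 32 per axis; the value is
a precision parameter, not an information parameter) and cosine tuning
r_k = (1 + cos(p − φ_k))/2 — the exact 1D marginal of the three-cosine
hexagonal rate map onto a principal axis.

**Distance cells.** One cell per location ℓ ∈ {0, δ, …, C−δ}
(δ = s_M/4 by default), with grid→distance weights equal to each bin's
rate at ℓ, rows normalized to max 1. Winner-take-all picks the argmax of
weights·rates (ties to the smallest ℓ). Two arrays (current, goal) feed
"move up"/"move down" readout neurons with linear weights of opposite
slope (goal: ℓ/C up, current: (C−ℓ)/C up; mirrored for down), the winner
contributing activation 1, so (up − down)·C/2 = ℓ_goal − ℓ_current
exactly; the readout inversion uses this constructed calibration rather
than a learned mapping (weight learning is out of scope). Per-axis error
bound: δ (two independent δ-grid quantizations of the two locations).

**Rate-coded vector cells.** One cell per displacement bin in
[−C/2, C/2) at δ_v = s_M/4. Cell d pairs current bin k with the goal bin
nearest φ_k + 2πd/s_i in every module (exactly m_i pairs per module);
drive is the sum over pairs of products of pre-synaptic rates
(multiplicative synapses taken as the computational contract), which
equals a circular cross-correlation of the two population vectors
evaluated at the cell's shift. Per-axis error bound:
δ_v/2 + max_i s_i/(2m_i) — displacement-grid quantization plus the
snapping of the shift to the phase-bin grid. The optional
variable-resolution mode thins bins so spacing grows as
δ_v(d) = δ_0·max(1, |d|/s_1); coarse far cells keep exact residue pair
tables, so off-bin far displacements may decode to an alias — the
intended operating mode is iterative re-decoding while moving, which
converges because bins near d = 0 stay at full resolution (verified in
tests; window- and max-pooled pair tables were tried and alias worse).

**Phase-coded vector cells.** With linear, axis-aligned precession
spanning the full theta cycle over one tile (π at field entry, 0 at the
centre, −π at exit), the theta phase of a goal-coding cell is
∅ = wrap(Δp) into (−π, π]; positive = later in the cycle, forced by the
convention that a goal less than half a scale ahead fires after the
current-location cells (which fire at the trough, 0). Templates over
displacement bins are matched by summed squared circular distance;
matches within 10⁻⁹ rad² of each other are flagged ambiguous and the
smaller |d| returned. The template range is (−C/2, C/2], closed on the
positive side, so a displacement of exactly half the capacity is
reported with positive sign (the two signs are the same displacement
modulo C). Spikes are abstract (module, theta-phase, goal-tag) events;
demultiplexing of simultaneously represented goals is by explicit tags,
as the biological mechanism is unspecified. Per-axis error bound: half a
template bin.

**Linear look-ahead.** The start code's axis phases advance by
2π·step/s_i per step (default step s_M/40 = 0.5 cm; must be ≤ s_M/8);
coincidence fires at the first step where the circular phase error to
the target is within tol in *all* modules (default tol: half the phase
bin of the smallest module, π/m). Sweeps run in both directions to C/2
and the nearer hit sets the sign. The step count is the latency readout
and is proportional to distance with zero intercept — the model's
defining prediction. During an axis-1 sweep, axis-2 phases are untouched
(phase "bands"). Per-axis error: the coincidence window,
tol·s_M/2π + step/2 (≈ 0.56 cm at defaults). Sweeps operate on phase
codes directly (an abstract attractor bump); no rate-sheet or oscillator
dynamics are simulated, since the model's content is the search scheme,
not the bump mechanism.

## Synthetic benchmark

`random_scenarios` draws starts uniformly over a C×C work area and axis
displacements uniformly in (−C/2, C/2) per axis — the full unambiguous
range, with no margin. Phase noise is von Mises jitter applied to every
phase (κ → ∞ is the identity; κ ≈ 1/σ² for small jitter); Gaussian rate
noise truncated at zero is available for rate-level experiments but the
standard matrix perturbs phases, since all decoders consume phase codes
at their interface. A single seeded generator drives everything; outputs
are byte-identical across runs at a fixed seed.

`run_matrix` scores each decode by per-axis circular error and flags
success if every axis error is within max(model bound, s_M/4). What the
generator does *not* emulate: real grid data's drift, boundary-induced
distortions, module-to-module orientation scatter beyond the configured
values, spiking variability, and theta-cycle sampling. Passing tests
therefore show the decoding schemes are correct and mutually consistent
under the idealized code, not that biological grid cells achieve these
accuracies.

## Numerical conventions and degenerate inputs

* Phases wrap to [0, 2π) with a guard against floating-point `mod`
  returning exactly 2π; theta phases and circular errors use (−π, π].
* Phase-equality tolerance 10⁻⁹ rad throughout.
* Ties: WTA ties break to the smallest preferred location (distance
  cells) or smallest |d| (vector cells); equal-latency bidirectional
  sweeps report the positive direction.
* Collinear axes (separation 0 or π), non-ordered scales, and empty
  systems are configuration errors; an infinite system period is an
  error for the network builders (they must tile [0, C)) and a sentinel
  (∞) from `system_period`.
* A look-ahead coincidence at step 0 for a target several steps away
  triggers a tolerance warning; a step-0 hit for a genuinely nearby
  target is legitimate and silent.

## Problem sizes

Defaults used by the test-suite and benchmark runs: scales {50, 30, 20}
cm (C = 300 cm), m_i = 32, δ = δ_v = 5 cm, look-ahead step 0.5 cm; 500
random scenarios for the cross-model consensus run, 100 for oracle
equivalence (oracle resolution 1 cm), 50 sweeps for the latency fit.
These sizes give machine-precision or quantization-limited results and
complete in seconds; larger systems scale as O(C/δ) cells per array and
O(C²/r²) oracle points.

## Known limitations

* Hebbian/developmental learning of all weight structures is
  deliberately out of scope; weights are constructed from their defining
  rules.
* The distance-cell readout uses unbounded linear rates (no
  saturation).
* WTA competition is scoped within each axis array; cross-axis
  competition is not modelled.
* The general (non-shared-axes) plane fit bounds its search by the
  pooled-scale period, a heuristic when module axes differ; capacity for
  incommensurate orientations is not characterized.
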