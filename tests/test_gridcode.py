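"""Forward model: axis projection, phase encoding, rate maps."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gridnav as gn
from gridnav.gridcode import (
    TWO_PI,
    GridModule,
    offset_grid,
    population_activity,
    wrap_phase,
    wrap_signed,
)

PI = math.pi


# ---------------------------------------------------------------------------
# axis projection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "xy, expected",
    [
        ((1.0, 0.0), (1.0, 0.0)),  # on the first axis
        # x̂ + ŷ with 60° separation: (1.5, √3/2)
        ((1.5, math.sqrt(3) / 2), (1.0, 1.0)),
        # inverting the 2×2 basis by hand for loc (0, 1)
        ((0.0, 1.0), (-1 / math.sqrt(3), 2 / math.sqrt(3))),
    ],
)
def test_project_onto_axes_examples(sys3, xy, expected):
    u, v = gn.project_onto_axes(gn.Location(*xy), sys3)
    assert u == pytest.approx(expected[0], abs=1e-12)
    assert v == pytest.approx(expected[1], abs=1e-12)


@given(x=st.floats(-500, 500), y=st.floats(-500, 500))
def test_basis_round_trip(sys3, x, y):
    """Projection followed by reconstruction through the basis is identity."""
    u, v = gn.project_onto_axes(gn.Location(x, y), sys3)
    rec = sys3.basis @ np.array([u, v])
    assert np.allclose(rec, [x, y], atol=1e-12 * max(1.0, abs(x), abs(y)))


def test_collinear_axes_rejected():
    with pytest.raises(gn.ConfigurationError):
        GridModule(scale=50.0, axis_separation=0.0)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "d, scale, expected",
    [
        (75.0, 50.0, PI),          # 75 mod 50 = 25 → half a tile
        (0.0, 50.0, 0.0),
        (25.0, 30.0, 5 * PI / 3),  # 25/30 of a tile
    ],
)
def test_encode_1d_examples(d, scale, expected):
    system = gn.from_scales([scale])
    code = gn.encode_location(gn.Location(d, 0.0), system)
    assert code.phases[0, 0] == pytest.approx(expected, abs=1e-12)


def test_encode_worked_example_1d_set(sys3, axis_loc):
    code = gn.encode_location(axis_loc(sys3, 75.0), sys3)
    assert np.allclose(code.phases[:, 0], [PI, PI, 1.5 * PI], atol=1e-9)


@given(
    u=st.floats(-300, 300),
    v=st.floats(-300, 300),
    k=st.integers(-3, 3),
    mod_idx=st.integers(0, 2),
    axis=st.integers(0, 1),
)
def test_wrap_correctness(sys3, axis_loc, u, v, k, mod_idx, axis):
    """Moving k whole scales along an axis leaves that module's phase fixed."""
    s = sys3.modules[mod_idx].axis_scales[axis]
    shift = [0.0, 0.0]
    shift[axis] = k * s
    c1 = gn.encode_location(axis_loc(sys3, u, v), sys3)
    c2 = gn.encode_location(axis_loc(sys3, u + shift[0], v + shift[1]), sys3)
    d = abs(wrap_signed(c2.phases[mod_idx, axis] - c1.phases[mod_idx, axis]))
    assert d < 1e-9


# ---------------------------------------------------------------------------
# phase differences
# ---------------------------------------------------------------------------

def test_phase_difference_identity(sys3, axis_loc):
    c = gn.encode_location(axis_loc(sys3, 12.3, 4.5), sys3)
    assert np.allclose(gn.phase_difference(c, c).dphases, 0.0)


def test_phase_difference_worked_example_values(sys3, axis_loc):
    a = gn.encode_location(axis_loc(sys3, 0.0), sys3)
    b = gn.encode_location(axis_loc(sys3, 75.0), sys3)
    dp = gn.phase_difference(a, b)
    assert np.allclose(dp.dphases[:, 0], [PI, PI, 1.5 * PI], atol=1e-9)
    # same displacement from a shifted start → identical differences
    a2 = gn.encode_location(axis_loc(sys3, 10.0), sys3)
    b2 = gn.encode_location(axis_loc(sys3, 85.0), sys3)
    dp2 = gn.phase_difference(a2, b2)
    assert np.allclose(dp.dphases, dp2.dphases, atol=1e-9)


@given(
    ax=st.floats(-200, 200), ay=st.floats(-200, 200),
    dx=st.floats(-140, 140), dy=st.floats(-140, 140),
)
def test_translation_invariance(sys3, ax, ay, dx, dy):
    """Phase differences depend only on the displacement b − a."""
    a1, b1 = gn.Location(ax, ay), gn.Location(ax + dx, ay + dy)
    a2, b2 = gn.Location(0.0, 0.0), gn.Location(dx, dy)
    dp1 = gn.phase_difference(gn.encode_location(a1, sys3), gn.encode_location(b1, sys3))
    dp2 = gn.phase_difference(gn.encode_location(a2, sys3), gn.encode_location(b2, sys3))
    err = np.abs(wrap_signed(dp1.dphases - dp2.dphases))
    assert err.max() < 1e-8


def test_module_count_mismatch_rejected(sys3, sys2, axis_loc):
    a = gn.encode_location(gn.Location(0, 0), sys3)
    b = gn.encode_location(gn.Location(0, 0), sys2)
    with pytest.raises(ValueError):
        gn.phase_difference(a, b)


# ---------------------------------------------------------------------------
# rate maps and population activity
# ---------------------------------------------------------------------------

def test_rate_map_field_center_and_antinode():
    mod = GridModule(scale=40.0)
    A = mod.lattice_basis
    # a field center of the zero-offset cell
    center = A @ np.array([2.0, -1.0])
    assert gn.rate_map((0.0, 0.0), gn.Location(*center), mod) == pytest.approx(1.0)
    # centroid of three adjacent field centers is the minimum of the pattern
    centroid = A @ np.array([1 / 3, 1 / 3])
    assert gn.rate_map((0.0, 0.0), gn.Location(*centroid), mod) == pytest.approx(
        0.0, abs=1e-12
    )


@given(u=st.floats(-3, 3), v=st.floats(-3, 3), k1=st.integers(-2, 2), k2=st.integers(-2, 2))
def test_rate_map_lattice_periodicity(u, v, k1, k2):
    mod = GridModule(scale=40.0)
    A = mod.lattice_basis
    x = A @ np.array([u, v])
    x2 = x + A @ np.array([k1, k2])
    r1 = gn.rate_map((1.0, 2.0), gn.Location(*x), mod)
    r2 = gn.rate_map((1.0, 2.0), gn.Location(*x2), mod)
    assert r1 == pytest.approx(r2, abs=1e-9)


def test_population_activity_bump_tracks_encoding():
    mod = GridModule(scale=40.0, cells_per_axis=16)
    system = gn.GridSystem(modules=(mod,))
    # at the origin the zero-offset cell wins
    rates = population_activity(gn.Location(0.0, 0.0), mod)
    assert np.argmax(rates) == 0
    # half a tile along axis 1 → argmax offset (π, 0) within one grid step
    x = mod.lattice_basis @ np.array([0.5, 0.0])
    loc = gn.Location(*x)
    rates = population_activity(loc, mod)
    best = offset_grid(mod)[np.argmax(rates)]
    code = gn.encode_location(loc, system)
    step = TWO_PI / mod.cells_per_axis
    assert abs(wrap_signed(best[0] - code.phases[0, 0])) <= step / 2 + 1e-9
    assert abs(wrap_signed(best[1] - code.phases[0, 1])) <= step / 2 + 1e-9


def test_population_activity_mass_invariant():
    """Total bump mass does not change as the bump moves over the sheet."""
    mod = GridModule(scale=40.0, cells_per_axis=16)
    totals = [
        population_activity(gn.Location(x, y), mod).sum()
        for x, y in [(0, 0), (3.7, -1.2), (19.9, 5.0), (-80.1, 33.3)]
    ]
    assert np.allclose(totals, totals[0], rtol=1e-9)


def test_wrap_phase_edge_cases():
    assert wrap_phase(-1e-20) == 0.0
    assert wrap_phase(TWO_PI) == 0.0
    assert wrap_signed(PI) == pytest.approx(PI)
    assert wrap_signed(PI + 1e-6) == pytest.approx(-PI + 1e-6)


def test_invalid_system_configurations():
    with pytest.raises(gn.ConfigurationError):
        gn.from_scales([20.0, 50.0])  # wrong ordering
    with pytest.raises(gn.ConfigurationError):
        gn.GridSystem(modules=())
    with pytest.raises(gn.ConfigurationError):
        gn.GridSystem(
            modules=(GridModule(50.0, orientation=0.0), GridModule(30.0, orientation=0.3)),
            shared_axes=True,
        )
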