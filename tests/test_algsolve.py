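"""Algorithmic decoder: capacity, unwrapping, line/plane fits, oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gridnav as gn
from gridnav import algsolve
from gridnav.gridcode import GridModule, GridSystem, PhaseDiff, wrap_phase

PI = math.pi


def dp_from_axis(values, axis=0, n_modules=None):
    values = np.asarray(values, dtype=float)
    n = n_modules or values.size
    arr = np.zeros((n, 2))
    arr[:, axis] = values
    return PhaseDiff(wrap_phase(arr))


# ---------------------------------------------------------------------------
# system period (capacity)
# ---------------------------------------------------------------------------

def test_system_period_examples(sys3, sys2):
    assert gn.system_period(gn.from_scales([42.0])) == pytest.approx(42.0)
    assert gn.system_period(sys3) == pytest.approx(300.0)
    assert gn.system_period(sys2) == pytest.approx(60.0)


def test_system_period_scan_confirms_lcm(sys3):
    C = gn.system_period(sys3, method="scan", resolution=1.0, max_range=2000.0)
    assert C == pytest.approx(300.0, abs=0.5)


def test_system_period_aperiodic_sentinel():
    system = gn.from_scales([50.0, 50.0 / math.sqrt(2)])
    C = gn.system_period(system, method="scan", resolution=0.5, max_range=500.0,
                         phase_tol=1e-9)
    assert C == math.inf


def test_fewer_modules_shrink_capacity(sys3, sys2):
    """Dropping the largest module shrinks the first ambiguous distance."""
    assert gn.system_period(sys3) > gn.system_period(sys2)


# ---------------------------------------------------------------------------
# unwrap candidates
# ---------------------------------------------------------------------------

def test_unwrap_zero_includes_origin(sys3):
    cands = gn.unwrap_candidates(dp_from_axis([0.0, 0.0, 0.0]), sys3)
    assert any(c.n == (0, 0, 0) for c in cands)


def test_unwrap_worked_example_candidate(sys3):
    """n = {1, 2, 3} unwraps {π, π, 3π/2} onto the d = 75 line."""
    cands = gn.unwrap_candidates(dp_from_axis([PI, PI, 1.5 * PI]), sys3)
    match = [c for c in cands if c.n == (1, 2, 3)]
    assert len(match) == 1
    # 2π·75/s_i for each module
    expected = 2 * PI * 75.0 / sys3.scales
    assert np.allclose(match[0].unwrapped, expected, atol=1e-9)


def test_unwrap_candidate_count_bounds(sys3):
    cands = gn.unwrap_candidates(dp_from_axis([PI, PI, 1.5 * PI]), sys3)
    C, s1, sM = 300.0, 50.0, 20.0
    n_max = math.ceil(C / sM) + 1
    assert len(cands) <= (2 * n_max + 1) ** 3
    assert len(cands) >= C / s1


# ---------------------------------------------------------------------------
# 1D line fit
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dpx, expected",
    [
        ([PI, PI, 1.5 * PI], 75.0),
        ([0.0, 0.0, 0.0], 0.0),
        ([PI, 5 * PI / 3, PI / 2], 25.0),  # forward-encode of d = 25
    ],
)
def test_decode_1d_examples(sys3, dpx, expected):
    report = gn.decode_1d_linefit(dp_from_axis(dpx), sys3)
    assert report.success
    assert report.vector.d_axis1 == pytest.approx(expected, abs=1e-6)
    assert report.residual < 1e-9


@given(d=st.floats(-149.9, 149.9))
def test_decode_1d_round_trip(sys3, d):
    dpx = wrap_phase(2 * PI * d / sys3.scales)
    report = gn.decode_1d_linefit(dp_from_axis(dpx), sys3)
    assert report.success
    assert report.vector.d_axis1 == pytest.approx(d, abs=1e-6)


# ---------------------------------------------------------------------------
# 2D plane fit
# ---------------------------------------------------------------------------

def test_decode_2d_worked_example(sys3):
    dp = PhaseDiff(np.column_stack([
        [PI, PI, 1.5 * PI],
        [1.5 * PI, 0.5 * PI, 1.75 * PI],
    ]))
    report = gn.decode_2d_planefit(dp, sys3)
    assert report.success
    assert report.vector.d_axis1 == pytest.approx(75.0, abs=1e-6)
    assert report.vector.d_axis2 == pytest.approx(37.5, abs=1e-6)


def test_decode_2d_zero(sys3):
    report = gn.decode_2d_planefit(PhaseDiff(np.zeros((3, 2))), sys3)
    assert report.vector.d_axis1 == 0.0 and report.vector.d_axis2 == 0.0


def test_decode_2d_random_round_trip(sys3, axis_loc):
    """200 random in-capacity displacements recover exactly, noise-free."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        u, v = rng.uniform(-149.5, 149.5, size=2)
        a = axis_loc(sys3, *rng.uniform(0, 300, size=2))
        b = gn.Location(*(a.xy + sys3.basis @ np.array([u, v])))
        dp = gn.phase_difference(
            gn.encode_location(a, sys3), gn.encode_location(b, sys3)
        )
        report = gn.decode_2d_planefit(dp, sys3)
        assert report.success
        assert report.vector.d_axis1 == pytest.approx(u, abs=1e-6)
        assert report.vector.d_axis2 == pytest.approx(v, abs=1e-6)


def test_decode_aliased_displacements_agree(sys3, axis_loc):
    """d and d + C produce the same phase code, hence the same decode."""
    a = gn.encode_location(axis_loc(sys3, 0.0), sys3)
    b1 = gn.encode_location(axis_loc(sys3, 40.0), sys3)
    b2 = gn.encode_location(axis_loc(sys3, 40.0 + 300.0), sys3)
    r1 = gn.decode_2d_planefit(gn.phase_difference(a, b1), sys3)
    r2 = gn.decode_2d_planefit(gn.phase_difference(a, b2), sys3)
    assert r1.vector.d_axis1 == pytest.approx(r2.vector.d_axis1, abs=1e-6)


def test_general_planefit_agrees_with_separable_path(sys3):
    """The general plane fit reproduces the per-axis path on shared axes."""
    dp = PhaseDiff(np.column_stack([
        [PI, PI, 1.5 * PI],
        [1.5 * PI, 0.5 * PI, 1.75 * PI],
    ]))
    general = algsolve._decode_2d_general(dp, sys3, 1e-6)
    assert general.success
    assert general.vector.d_axis1 == pytest.approx(75.0, abs=1e-6)
    assert general.vector.d_axis2 == pytest.approx(37.5, abs=1e-6)


def test_general_planefit_rotated_modules():
    """Modules with differing orientations still decode via the plane fit."""
    mods = (
        GridModule(50.0, orientation=0.0),
        GridModule(30.0, orientation=0.12),
        GridModule(20.0, orientation=-0.2),
    )
    system = GridSystem(modules=mods, shared_axes=False)
    rng = np.random.default_rng(3)
    for _ in range(5):
        d = rng.uniform(-18, 18, size=2)
        a = gn.Location(*rng.uniform(0, 100, size=2))
        b = gn.Location(*(a.xy + d))
        dp = gn.phase_difference(
            gn.encode_location(a, system), gn.encode_location(b, system)
        )
        report = gn.decode_2d_planefit(dp, system)
        assert report.success
        assert np.allclose(report.vector.cartesian, d, atol=1e-6)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def test_oracle_worked_example(sys3):
    dp = dp_from_axis([PI, PI, 1.5 * PI])
    vec = gn.brute_force_oracle(dp, sys3, resolution=1.0)
    assert abs(vec.d_axis1 - 75.0) <= 1.0


def test_oracle_matches_planefit(sys3, axis_loc):
    rng = np.random.default_rng(11)
    for _ in range(25):
        u, v = rng.uniform(-149.0, 149.0, size=2)
        a = axis_loc(sys3, 0.0, 0.0)
        b = axis_loc(sys3, u, v)
        dp = gn.phase_difference(
            gn.encode_location(a, sys3), gn.encode_location(b, sys3)
        )
        vec = gn.brute_force_oracle(dp, sys3, resolution=1.0)
        rep = gn.decode_2d_planefit(dp, sys3)
        assert abs(vec.d_axis1 - rep.vector.d_axis1) <= 1.0
        assert abs(vec.d_axis2 - rep.vector.d_axis2) <= 1.0


def test_oracle_and_planefit_agree_under_noise(sys3):
    """With σ ≈ 0.2 rad phase jitter both decoders pick the same candidate
    in ≥ 95% of trials (wrapped-Gaussian jitter on each phase)."""
    rng = np.random.default_rng(42)
    agree = 0
    n_trials = 500
    for _ in range(n_trials):
        d = rng.uniform(-140.0, 140.0, size=2)
        clean = np.column_stack([2 * PI * d[0] / sys3.scales,
                                 2 * PI * d[1] / sys3.scales])
        noisy = PhaseDiff(wrap_phase(clean + rng.normal(0.0, 0.2, size=clean.shape)))
        vec = gn.brute_force_oracle(noisy, sys3, resolution=1.0)
        rep = gn.decode_2d_planefit(noisy, sys3, residual_threshold=1.0)
        if (abs(vec.d_axis1 - rep.vector.d_axis1) <= 2.0
                and abs(vec.d_axis2 - rep.vector.d_axis2) <= 2.0):
            agree += 1
    assert agree / n_trials >= 0.95


def test_oracle_resolution_guard(sys3):
    with pytest.raises(ValueError):
        gn.brute_force_oracle(dp_from_axis([0, 0, 0]), sys3, resolution=5.0)
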