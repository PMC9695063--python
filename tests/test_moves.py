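"""Move set: selection statistics, free rotation intervals, screening."""

import numpy as np
import pytest

from conftest import random_chain
from knotfold import _kernels
from knotfold.model import Conformation, ModelParams
from knotfold.moves import (MoveProposal, apply_and_screen,
                            free_rotation_interval,
                            max_moving_beads, min_crossing_safe_radius,
                            min_nonadjacent_stick_distance, propose_angle,
                            select_move)


def _scan_free_interval(coords, prop, radius, resolution=1e-3):
    """Dense-scan oracle: the connected clash-free arc containing angle 0.

    Scans the full circle in both directions (the analytic arc may extend
    beyond +-pi); an entirely clash-free circle reports (-pi, pi).
    """
    angles = np.arange(0.0, 2 * np.pi + resolution, resolution)
    a = prop.axis_point
    u = prop.axis_dir

    def clash_at(angle):
        trial = coords.copy()
        _kernels.rotate_range(trial, prop.moving_start, prop.moving_end,
                              a[0], a[1], a[2], u[0], u[1], u[2], angle)
        return _kernels.has_clash_moving(trial, prop.moving_start,
                                         prop.moving_end, radius)

    hi = lo = None
    for ang in angles:
        if clash_at(ang):
            hi = ang
            break
    for ang in angles:
        if clash_at(-ang):
            lo = -ang
            break
    if hi is None and lo is None:
        return -np.pi, np.pi
    return lo, hi


def test_moving_set_size_range_and_kind_frequencies():
    """Kinds drawn with p=0.5 each; m uniform on {1..m_max}, m_max the
    largest integer strictly below 3N/4 (N=8 -> {1..5})."""
    assert max_moving_beads(8) == 5
    assert max_moving_beads(15) == 11
    assert max_moving_beads(4) == 2
    rng = np.random.default_rng(0)
    coords = random_chain(rng, 8)
    kinds = {"crankshaft": 0, "pivot": 0}
    sizes = set()
    n_draw = 100000
    for _ in range(n_draw):
        prop = select_move(coords, rng)
        kinds[prop.kind] += 1
        sizes.add(prop.moving_size)
    assert sizes == {1, 2, 3, 4, 5}
    assert abs(kinds["crankshaft"] / n_draw - 0.5) < 0.01


def test_smallest_pivot_moves_only_the_terminal_bead():
    rng = np.random.default_rng(3)
    coords = random_chain(rng, 8)
    for _ in range(200):
        prop = select_move(coords, rng)
        if prop.kind == "pivot" and prop.moving_size == 1:
            assert prop.moving_start in (0, 7)
            axis_bead = 1 if prop.moving_start == 0 else 6
            assert np.allclose(prop.axis_point, coords[axis_bead])
            prop.angle = 1.0
            trial = apply_and_screen(coords, prop, ModelParams())
            moved = np.linalg.norm(trial.coords - coords, axis=1) > 1e-12
            assert moved.sum() <= 1
            assert not moved[1:-1].any()
            break
    else:
        pytest.fail("no single-bead pivot drawn")


def test_crankshaft_axis_through_flanking_beads():
    rng = np.random.default_rng(5)
    coords = random_chain(rng, 10)
    for _ in range(100):
        prop = select_move(coords, rng)
        if prop.kind == "crankshaft":
            s, e = prop.moving_start, prop.moving_end
            assert 1 <= s and e <= 9
            assert np.allclose(prop.axis_point, coords[s - 1])
            d = coords[e] - coords[s - 1]
            d /= np.linalg.norm(d)
            assert np.allclose(np.abs(prop.axis_dir @ d), 1.0, atol=1e-12)
            break
    else:
        pytest.fail("no crankshaft drawn")


def test_free_interval_full_circle_when_no_collision_possible():
    # short chain widely separated from the moving bead's orbit
    coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0],
                       [15.2, 0, 0.0]])
    prop = MoveProposal(kind="crankshaft", axis_point=coords[1],
                        axis_dir=np.array([1.0, 0, 0]), moving_start=2,
                        moving_end=3)
    lo, hi = free_rotation_interval(coords, prop, ModelParams())
    assert (lo, hi) == (-np.pi, np.pi)


def test_free_interval_law_of_cosines_single_pair():
    """One moving bead on a circle of radius R, one coplanar fixed bead at
    axis distance D: contact at azimuth +-arccos((R^2+D^2-c^2)/(2RD))."""
    radius = 1.7
    c = 2 * radius
    r_orbit, d_fixed = 5.0, 4.0
    # axis along z through origin; moving bead at azimuth 0, fixed at pi
    coords = np.zeros((6, 3))
    coords[0] = [r_orbit, 0, 30]     # chain padding far away
    coords[1] = [r_orbit, 0, 15]
    coords[2] = [r_orbit, 0, 0]      # moving bead, orbit radius 5
    coords[3] = [r_orbit, 0, -15]
    coords[4] = [-d_fixed, 0, 0]     # fixed bead in the rotation plane
    coords[5] = [-d_fixed, 0, -15]
    prop = MoveProposal(kind="pivot", axis_point=np.zeros(3),
                        axis_dir=np.array([0, 0, 1.0]), moving_start=2,
                        moving_end=3)
    lo, hi = free_rotation_interval(coords, prop, ModelParams())
    beta = np.arccos((r_orbit ** 2 + d_fixed ** 2 - c ** 2)
                     / (2 * r_orbit * d_fixed))
    # fixed bead azimuth is pi; free arc ends where |pi - alpha| = beta
    assert hi == pytest.approx(np.pi - beta, abs=1e-9)
    assert lo == pytest.approx(-(np.pi - beta), abs=1e-9)


@pytest.mark.parametrize("seed", range(12))
def test_free_interval_matches_dense_scan(seed):
    """Closed-form interval endpoints agree with a 1e-3 rad dense scan, and
    the returned arc is clash-free everywhere."""
    rng = np.random.default_rng(seed)
    params = ModelParams()
    coords = random_chain(rng, 10)
    prop = select_move(coords, rng)
    lo, hi = free_rotation_interval(coords, prop, params)
    slo, shi = _scan_free_interval(coords, prop, params.bead_radius)
    assert hi == pytest.approx(shi, abs=2e-3)
    assert lo == pytest.approx(slo, abs=2e-3)
    # min distance over the returned interval respects the contact distance
    a, u = prop.axis_point, prop.axis_dir
    for ang in np.linspace(lo + 1e-9, hi - 1e-9, 50):
        trial = coords.copy()
        _kernels.rotate_range(trial, prop.moving_start, prop.moving_end,
                              a[0], a[1], a[2], u[0], u[1], u[2], ang)
        assert not _kernels.has_clash_moving(trial, prop.moving_start,
                                             prop.moving_end,
                                             params.bead_radius - 1e-9)


def test_ltyp_angles_stay_inside_interval_and_trials_never_clash():
    rng = np.random.default_rng(7)
    params = ModelParams()
    coords = random_chain(rng, 12)
    conf = Conformation(coords)
    for _ in range(2000):
        prop = select_move(conf, rng, ltyp=True)
        lo, hi = free_rotation_interval(conf, prop, params)
        ang = propose_angle(prop, rng)
        assert lo <= ang <= hi
        trial = apply_and_screen(conf, prop, params, check_ltyp=True)
        assert trial is not None
        conf = trial


def test_identity_rotation_returns_same_conformation():
    rng = np.random.default_rng(9)
    coords = random_chain(rng, 8)
    prop = select_move(coords, rng, ltyp=False)
    prop.angle = 0.0
    trial = apply_and_screen(coords, prop, ModelParams())
    assert np.allclose(trial.coords, coords, atol=1e-12)


def test_rotation_is_rigid():
    """Bond lengths and all pairwise distances inside the moving set are
    preserved to 1e-9 A."""
    rng = np.random.default_rng(13)
    coords = random_chain(rng, 12)
    bonds0 = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    for _ in range(50):
        prop = select_move(coords, rng, ltyp=False)
        propose_angle(prop, rng)
        trial = apply_and_screen(coords, prop, ModelParams())
        if trial is None:
            continue
        tb = np.linalg.norm(np.diff(trial.coords, axis=0), axis=1)
        assert np.allclose(tb, bonds0, atol=1e-9)
        ms = slice(prop.moving_start, prop.moving_end)
        d0 = np.linalg.norm(coords[ms, None] - coords[None, ms][0], axis=-1)
        d1 = np.linalg.norm(trial.coords[ms, None]
                            - trial.coords[None, ms][0], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)
        coords = trial.coords


def test_non_ltyp_screen_rejects_endpoint_clashes():
    rng = np.random.default_rng(21)
    params = ModelParams()
    coords = random_chain(rng, 12)
    rejected = accepted = 0
    for _ in range(500):
        prop = select_move(coords, rng, ltyp=False)
        propose_angle(prop, rng)
        trial = apply_and_screen(coords, prop, params)
        if trial is None:
            rejected += 1
        else:
            accepted += 1
            assert not _kernels.has_clash_full(trial.coords,
                                               params.bead_radius)
            coords = trial.coords
    assert rejected > 0 and accepted > 0


def test_min_crossing_safe_radius_value():
    """Worst intersecting geometry of two 3.9 A sticks: perpendicular
    mid-mid crossing, safe radius 3.9*sqrt(2)/4 = 1.38 A (2 d.p.)."""
    r = min_crossing_safe_radius(3.9)
    assert round(r, 2) == 1.38
    assert r == pytest.approx(3.9 * np.sqrt(2) / 4, abs=1e-4)


def test_ltyp_rotation_path_never_crosses_sticks():
    """Along a dense scan of the free interval no two non-adjacent sticks
    approach within crossing distance: bead exclusion with radius 1.7 >=
    1.38 A forbids chain crossing."""
    rng = np.random.default_rng(31)
    params = ModelParams()
    for case in range(5):
        coords = random_chain(rng, 10)
        prop = select_move(coords, rng)
        lo, hi = free_rotation_interval(coords, prop, params)
        a, u = prop.axis_point, prop.axis_dir
        for ang in np.linspace(lo, hi, 80):
            trial = coords.copy()
            _kernels.rotate_range(trial, prop.moving_start, prop.moving_end,
                                  a[0], a[1], a[2], u[0], u[1], u[2], ang)
            assert min_nonadjacent_stick_distance(trial) > 0.5
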