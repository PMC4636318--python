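import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tmdistort.helix_geometry import (
    bend_angle,
    classify_distortion,
    detect_pivot,
    fit_axis,
)
from tmdistort.structio import Atom, Frame, Residue
from tmdistort.synthetic_data import (
    HelixSpec,
    TrajectorySpec,
    make_bulged_helix,
    make_ideal_helix,
    make_kinked_helix,
    make_trajectory,
)


def brute_force_line_direction(points):
    """Independent oracle: minimise total squared perpendicular distance over
    spherical direction angles, multi-start."""
    pts = points - points.mean(axis=0)

    def cost(angles):
        t, p = angles
        d = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
        return np.sum(np.sum(pts**2, axis=1) - (pts @ d) ** 2)

    best = None
    for t0 in (0.5, 1.5, 2.5):
        for p0 in (0.5, 2.0, 4.0):
            res = minimize(cost, [t0, p0], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
    t, p = best.x
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_fit_axis_matches_brute_force_on_random_points(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(8, 3)) * [5.0, 1.0, 1.0]
    direction = fit_axis(pts).direction
    oracle = brute_force_line_direction(pts)
    assert abs(abs(np.dot(direction, oracle)) - 1.0) < 1e-5


def test_arm_axis_on_ideal_arm_parallel_to_construction():
    from tmdistort.helix_geometry import arm_axis

    frame = make_ideal_helix(HelixSpec(30))
    ca = np.array([r.coord("CA") for r in frame.chain("A")])
    whole = arm_axis(ca).direction
    arm = arm_axis(ca[:10]).direction
    # the one-turn-smoothed arm estimator removes the helical-phase tilt a
    # raw line fit picks up on short arms
    assert np.degrees(np.arccos(np.clip(abs(np.dot(whole, arm)), -1, 1))) < 1.0


def test_fit_axis_orientation_flips_with_point_order():
    rng = np.random.default_rng(0)
    pts = np.outer(np.arange(8), [1.0, 0.2, -0.1]) + rng.normal(0, 0.01, (8, 3))
    fwd = fit_axis(pts).direction
    rev = fit_axis(pts[::-1]).direction
    assert np.allclose(fwd, -rev)


def test_fit_axis_collinear_points_exact():
    direction = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
    pts = np.outer(np.arange(7), direction)
    assert abs(abs(np.dot(fit_axis(pts).direction, direction)) - 1.0) < 1e-12


def test_fit_axis_requires_six_points():
    with pytest.raises(ValueError):
        fit_axis(np.zeros((5, 3)))


def test_bend_angle_rigid_motion_invariant(kinked30):
    rng = np.random.default_rng(4)
    a = bend_angle(kinked30, (1, 30), 15)
    moved = kinked30.copy()
    moved.set_coords(Rotation.random(random_state=rng).apply(moved.coords()) + 13.0)
    assert abs(bend_angle(moved, (1, 30), 15) - a) < 1e-6


def test_bend_angle_arm_too_short_mentions_span():
    frame = make_ideal_helix(HelixSpec(20))
    with pytest.raises(ValueError, match="span"):
        bend_angle(frame, (1, 20), 3)


def test_bend_angle_noisy_recovery_20_seeds():
    errors = []
    for seed in range(20):
        base = make_kinked_helix(HelixSpec(30), 30.0, 15)
        frame = make_trajectory(base, TrajectorySpec(1, 0.15, None, seed=seed))[0]
        errors.append(abs(bend_angle(frame, (1, 30), 15) - 30.0))
    assert np.mean(errors) < 4.0


def test_detect_pivot_finds_programmed_hinge(kinked30):
    assert abs(detect_pivot(kinked30, (1, 30)).index - 15) <= 1


def test_detect_pivot_straight_helix_small_angle(ideal30):
    assert detect_pivot(ideal30, (1, 30)).angle < 3.0


def test_detect_pivot_prefers_stronger_of_two_kinks():
    from tmdistort.synthetic_data import set_bend

    frame = make_ideal_helix(HelixSpec(45))
    frame = set_bend(frame, (1, 45), 15, 30.0)   # strong hinge early
    frame = set_bend(frame, (16, 45), 30, 10.0)  # weak hinge late
    assert abs(detect_pivot(frame, (1, 45)).index - 15) <= 1


def test_detect_pivot_requires_13_residues(ideal30):
    with pytest.raises(ValueError):
        detect_pivot(ideal30, (1, 12))


def test_classify_needs_some_evidence(ideal30):
    with pytest.raises(ValueError):
        classify_distortion(ideal30, (1, 30))


def test_classify_straight_from_register(ideal30):
    from tmdistort.hbond_register import register_profile

    rp = register_profile(ideal30, (1, 30))
    assert classify_distortion(ideal30, (1, 30), register=rp).verdict == "straight"


def test_classify_kink_from_register(kinked30):
    from tmdistort.hbond_register import register_profile

    rp = register_profile(kinked30, (1, 30))
    call = classify_distortion(kinked30, (1, 30), register=rp)
    assert call.verdict == "kink"
    assert call.evidence["bend_angle_deg"] > 15.0


def _proline_geometry_frame(close_offsets):
    """Synthetic geometry: a fake proline whose ring atoms are placed near
    the carbonyl O of chosen upstream residues."""
    residues = []
    for i in range(1, 16):
        atoms = [
            Atom("N", "N", [1.5 * i, 0.0, 0.0]),
            Atom("CA", "C", [1.5 * i + 0.5, 1.0, 0.0]),
            Atom("C", "C", [1.5 * i + 1.0, 0.0, 0.0]),
            Atom("O", "O", [1.5 * i + 1.0, 0.0, 10.0 + i]),  # spread out
        ]
        residues.append(Residue(i, "ALA", atoms))
    pro = residues[-1]
    pro.name = "PRO"
    ring = []
    for k, name in zip((3, 4, 5), ("CB", "CG", "CD")):
        o = residues[15 - k - 1].atom("O").coord
        offset = 0.5 if k in close_offsets else 8.0
        ring.append(Atom(name, "C", o + [0.0, offset, 0.0]))
    pro.atoms.extend(ring)
    return Frame({"A": residues})


def test_proline_rule_kink_vs_bulge():
    kink_frame = _proline_geometry_frame(close_offsets={3, 4})
    call = classify_distortion(kink_frame, (1, 15), proline=15)
    assert call.verdict == "kink"
    bulge_frame = _proline_geometry_frame(close_offsets={4, 5})
    call = classify_distortion(bulge_frame, (1, 15), proline=15)
    assert call.verdict == "bulge"
    assert set(call.evidence["proline"]) == {"d_minus_3", "d_minus_4", "d_minus_5"}


def test_register_wins_on_conflict(bulged30):
    from tmdistort.hbond_register import register_profile

    # attach a fake proline whose ring sits near O(-3)/O(-4) => "kink",
    # while the register says "bulge"
    frame = bulged30.copy()
    pro = frame.residue(25)
    pro.name = "PRO"
    for k, name in zip((3, 4), ("CG", "CD")):
        o = frame.residue(25 - k).atom("O").coord
        pro.atoms.append(Atom(name, "C", o + [0.3, 0.3, 0.0]))
    rp = register_profile(frame, (1, 31))
    call = classify_distortion(frame, (1, 31), proline=25, register=rp)
    assert call.verdict == "bulge"
    assert call.conflict


def test_classification_accuracy_over_seeds():
    correct = 0
    bulged = make_bulged_helix(HelixSpec(30), 15)
    kinked = make_kinked_helix(HelixSpec(30), 30.0, 15)
    from tmdistort.hbond_register import register_profile

    for seed in range(20):
        fb = make_trajectory(bulged, TrajectorySpec(1, 0.15, None, seed=seed))[0]
        rp = register_profile(fb, (1, 31))
        correct += classify_distortion(fb, (1, 31), register=rp).verdict == "bulge"
        fk = make_trajectory(kinked, TrajectorySpec(1, 0.15, None, seed=seed + 100))[0]
        rp = register_profile(fk, (1, 30))
        correct += classify_distortion(fk, (1, 30), register=rp).verdict == "kink"
    assert correct >= 38  # ≥95% of 40 verdicts
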