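import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmdistort.hbond_register import detect_backbone_hbonds
from tmdistort.helix_geometry import bend_angle, classify_distortion
from tmdistort.synthetic_data import (
    ColumnProfile,
    HelixSpec,
    MsaSpec,
    TrajectorySpec,
    make_bulged_helix,
    make_ideal_helix,
    make_kinked_helix,
    make_msa,
    make_trajectory,
    set_bend,
)


def rigid_copy(frame, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng)
    out = frame.copy()
    out.set_coords(rot.apply(out.coords()) + rng.uniform(-20, 20, 3))
    return out


def test_spec_validation():
    with pytest.raises(ValueError):
        HelixSpec(5)
    with pytest.raises(ValueError):
        HelixSpec(10, sequence="AAA")
    with pytest.raises(ValueError):
        TrajectorySpec(0, 0.1, None, 0)
    with pytest.raises(ValueError):
        TrajectorySpec(2, -0.1, None, 0)
    with pytest.raises(ValueError):
        TrajectorySpec(2, 0.1, [10.0], 0)


def test_ideal_helix_is_straight(ideal30):
    assert bend_angle(ideal30, (1, 30), 15) < 3.0


def test_ideal_helix_full_i4_register(ideal30):
    bonds = detect_backbone_hbonds(ideal30)
    donors_i4 = sorted(b.donor_residue for b in bonds if b.offset == 4)
    assert donors_i4 == list(range(5, 31))
    assert not any(b.offset == 5 for b in bonds)


def test_ideal_helix_bend_rotation_invariant(ideal30):
    a = bend_angle(ideal30, (1, 30), 15)
    b = bend_angle(rigid_copy(ideal30), (1, 30), 15)
    assert abs(a - b) < 1e-6


@pytest.mark.parametrize("theta", [10, 20, 30, 40, 50])
def test_kink_angle_recovered(theta):
    frame = make_kinked_helix(HelixSpec(30), theta, 15)
    assert bend_angle(frame, (1, 30), 15) == pytest.approx(theta, abs=2.0)


def test_zero_kink_equals_ideal(ideal30):
    zero = make_kinked_helix(HelixSpec(30), 0.0, 15)
    assert np.abs(zero.coords() - ideal30.coords()).max() < 1e-6


def test_kink_arms_too_short_rejected():
    with pytest.raises(ValueError):
        make_kinked_helix(HelixSpec(12), 20.0, 4)


def test_bulge_register_contract(bulged30):
    bonds = detect_backbone_hbonds(bulged30)
    i5 = [b.donor_residue for b in bonds if b.offset == 5]
    assert any(13 <= d <= 17 for d in i5)
    i4 = {b.donor_residue for b in bonds if b.offset == 4}
    missing_near = [d for d in range(13, 18) if d not in i4]
    assert len(missing_near) >= 2


def test_bulge_has_one_extra_residue(bulged30):
    assert len(bulged30.chain("A")) == 31


def test_bulge_classifies_as_bulge(bulged30):
    from tmdistort.hbond_register import register_profile

    rp = register_profile(bulged30, (1, 31))
    assert classify_distortion(bulged30, (1, 31), register=rp).verdict == "bulge"


def test_no_bulge_means_no_i5(ideal30):
    assert not any(b.offset == 5 for b in detect_backbone_hbonds(ideal30))


def test_set_bend_hits_target(ideal30):
    bent = set_bend(ideal30, (1, 30), 15, 24.0)
    assert bend_angle(bent, (1, 30), 15) == pytest.approx(24.0, abs=1e-6)


def test_trajectory_schedule_recovered():
    base = make_kinked_helix(HelixSpec(30), 26.0, 15)
    spec = TrajectorySpec(5, 0.15, [26, 20, 14, 10, 10], seed=11)
    trace = bend_angle(make_trajectory(base, spec), (1, 30), 15)
    assert np.abs(trace.angles - [26, 20, 14, 10, 10]).max() < 3.0


def test_trajectory_zero_noise_constant_schedule_identical(ideal30):
    fs = make_trajectory(ideal30, TrajectorySpec(3, 0.0, None, seed=0))
    assert np.abs(fs[0].coords() - fs[2].coords()).max() == 0.0


def test_trajectory_deterministic(ideal30):
    spec = TrajectorySpec(3, 0.2, None, seed=5)
    a = make_trajectory(ideal30, spec)
    b = make_trajectory(ideal30, spec)
    for fa, fb in zip(a, b):
        assert np.array_equal(fa.coords(), fb.coords())


def test_trajectory_requires_pivot_for_bend_schedule(ideal30):
    with pytest.raises(ValueError, match="pivot"):
        make_trajectory(ideal30, TrajectorySpec(2, 0.0, [10.0, 20.0], seed=0))


def _msa_spec(seed=0, deletion=None):
    profiles = [ColumnProfile("L", 0.8) for _ in range(10)]
    profiles[3] = ColumnProfile("Y", 1.0)
    return MsaSpec(
        n_sequences=8,
        column_profiles=profiles,
        group_labels=["G1"] * 4 + ["G2"] * 4,
        anchor_columns={"5.39": 3},
        planted_deletion_column=deletion,
        deletion_group="G1" if deletion is not None else None,
        seed=seed,
    )


def test_msa_deterministic():
    a = make_msa(_msa_spec(seed=9))
    b = make_msa(_msa_spec(seed=9))
    assert a.records == b.records


def test_msa_full_conservation_column():
    aln = make_msa(_msa_spec())
    assert set(aln.column(3)) == {"Y"}


def test_msa_planted_deletion_gaps_only_the_deletion_group():
    aln = make_msa(_msa_spec(deletion=5))
    for sid, seq in aln.records:
        assert (seq[5] == "-") == sid.startswith("G1")


def test_msa_rejects_deletion_on_anchor():
    with pytest.raises(ValueError):
        make_msa(_msa_spec(deletion=3))
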