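"""Geometric pose criteria: distances, angles, classification, fractions."""

import numpy as np
import pytest

from p450select import (
    CriteriaConfig,
    DataFormatError,
    DataValidationError,
    PoseFrame,
    SomDefinition,
    active_fraction,
    classify_frame,
    fraction_report,
    frame_geometry,
    gen_pose_trajectory,
    read_pose_table,
    read_xyz_trajectory,
)
from p450select.synth import SyntheticPoseConfig

AROM = SomDefinition("arom", "aromatic", c_atom="C", h_atom="H")
ALIPH = SomDefinition("aliph", "aliphatic", h_atom="H")


def frame(**coords):
    return PoseFrame(0, {k: np.array(v, dtype=float) for k, v in coords.items()})


def aromatic_frame(distance, angle_at_h):
    """C on the z-axis at `distance` from O, H placed to give the target
    C-H-O angle (constructed with the synth helper's geometry)."""
    from p450select.synth import _place_h_for_angle

    o = np.zeros(3)
    c = np.array([0.0, 0.0, distance])
    h = _place_h_for_angle(o, c, angle_at_h)
    return frame(C=c, H=h, O_ferryl=o)


def aliphatic_frame(distance, angle_at_o):
    fe = np.array([0.0, 0.0, -0.163])
    theta = np.radians(angle_at_o)
    h = distance * np.array([np.sin(theta), 0.0, -np.cos(theta)])
    return frame(H=h, O_ferryl=[0, 0, 0], Fe=fe)


# ---------------------------------------------------------------------------
# geometry


def test_collinear_hydrogen_between_carbon_and_oxygen_is_180_degrees():
    f = frame(C=[0, 0, 0.3], H=[0, 0, 0.15], O_ferryl=[0, 0, 0])
    g = frame_geometry(f, AROM)
    assert g["angle"] == pytest.approx(180.0)
    assert g["distance"] == pytest.approx(0.30)


def test_right_angle_construction():
    f = frame(H=[0.1, 0, 0], O_ferryl=[0, 0, 0], Fe=[0, 0, -0.163])
    assert frame_geometry(f, ALIPH)["angle"] == pytest.approx(90.0)


def test_missing_atom_names_role_and_frame():
    f = frame(C=[0, 0, 0.3], O_ferryl=[0, 0, 0])
    with pytest.raises(DataValidationError, match=r"frame 0.*'H'"):
        frame_geometry(f, AROM)


# ---------------------------------------------------------------------------
# classification


def test_aromatic_active_when_close_and_angle_clear():
    assert classify_frame(aromatic_frame(0.30, 120.0), AROM)


def test_aromatic_hydrogen_interposition_excludes():
    assert not classify_frame(aromatic_frame(0.30, 160.0), AROM)
    assert not classify_frame(aromatic_frame(0.30, 180.0), AROM)


def test_aliphatic_distance_failure():
    assert not classify_frame(aliphatic_frame(0.40, 120.0), ALIPH)


def test_aliphatic_window_is_inclusive_and_distance_strict():
    assert classify_frame(aliphatic_frame(0.30, 110.0), ALIPH)
    assert classify_frame(aliphatic_frame(0.30, 130.0), ALIPH)
    assert not classify_frame(aliphatic_frame(0.30, 109.0), ALIPH)
    assert not classify_frame(aliphatic_frame(0.30, 131.0), ALIPH)
    # printed criterion is a strict '<' on the distance
    assert not classify_frame(aliphatic_frame(0.35, 120.0), ALIPH)


def test_aromatic_exclusion_onset_at_140_degrees():
    assert not classify_frame(aromatic_frame(0.30, 140.5), AROM)
    assert classify_frame(aromatic_frame(0.30, 139.0), AROM)


def test_classification_invariant_under_rigid_motion(rng):
    frames = [aromatic_frame(0.30, 120.0), aromatic_frame(0.30, 160.0),
              aliphatic_frame(0.30, 120.0), aliphatic_frame(0.40, 120.0)]
    soms = [AROM, AROM, ALIPH, ALIPH]
    for f, som in zip(frames, soms):
        before = classify_frame(f, som)
        g_before = frame_geometry(f, som)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        shift = rng.uniform(-3, 3, 3)
        moved = PoseFrame(0, {r: rot @ c + shift for r, c in f.coords.items()})
        assert classify_frame(moved, som) == before
        g_after = frame_geometry(moved, som)
        assert g_after["distance"] == pytest.approx(g_before["distance"], abs=1e-9)
        assert g_after["angle"] == pytest.approx(g_before["angle"], abs=1e-9)


def test_shrinking_cutoff_never_adds_active_frames():
    frames, _ = gen_pose_trajectory(SyntheticPoseConfig(n_frames=120, seed=7))
    som = SyntheticPoseConfig().soms[0]
    counts = []
    for cutoff in [0.6, 0.45, 0.35, 0.25, 0.15, 0.05]:
        cfg = CriteriaConfig(distance_cutoff=cutoff)
        counts.append(active_fraction(frames, som, cfg)[1])
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# fractions


def test_constructed_fraction_is_reported_exactly():
    frames, labels = gen_pose_trajectory(
        SyntheticPoseConfig(n_frames=100, target_fraction={"arom": 60.0, "aliph": 40.0}, seed=1)
    )
    som = SyntheticPoseConfig().soms[0]
    n, n_act, pct = active_fraction(frames, som)
    assert (n, n_act, pct) == (100, 60, 60.0)


def test_single_inactive_frame_is_zero_percent():
    assert active_fraction([aromatic_frame(0.50, 120.0)], AROM)[2] == 0.0


def test_all_identical_active_frames_are_100_percent():
    f = aromatic_frame(0.30, 120.0)
    assert active_fraction([f] * 5, AROM)[2] == 100.0


def test_empty_trajectory_is_an_error():
    with pytest.raises(DataValidationError, match="empty"):
        active_fraction([], AROM)


def test_disjoint_halves_average_to_whole(rng):
    frames, _ = gen_pose_trajectory(SyntheticPoseConfig(n_frames=100, seed=5))
    som = SyntheticPoseConfig().soms[1]
    n, k, whole = active_fraction(frames, som)
    n1, k1, p1 = active_fraction(frames[:37], som)
    n2, k2, p2 = active_fraction(frames[37:], som)
    assert (n1 * p1 + n2 * p2) / (n1 + n2) == pytest.approx(whole, abs=1e-12)


def test_report_pivot_has_trajectories_by_soms(rng):
    cfg = SyntheticPoseConfig(n_frames=50, seed=2)
    frames, _ = gen_pose_trajectory(cfg)
    rep = fraction_report({"A": frames, "B": frames[:25]}, cfg.soms)
    piv = rep.pivot()
    assert piv.shape == (2, 2)
    assert set(piv.columns) == {"arom", "aliph"}


# ---------------------------------------------------------------------------
# input formats


def test_pose_table_roundtrip_with_unit_column(tmp_path):
    f = aromatic_frame(0.30, 120.0)
    lines = ["frame,role,x,y,z,unit"]
    for role, xyz in f.coords.items():
        lines.append(f"0,{role},{xyz[0]},{xyz[1]},{xyz[2]},nm")
    p = tmp_path / "poses.csv"
    p.write_text("\n".join(lines) + "\n")
    frames = read_pose_table(p)
    assert len(frames) == 1
    assert classify_frame(frames[0], AROM)


def test_angstrom_rows_are_scaled_to_nm(tmp_path):
    p = tmp_path / "poses.csv"
    p.write_text("frame,role,x,y,z,unit\n0,C,3.0,0,0,angstrom\n0,O_ferryl,0,0,0,angstrom\n")
    frames = read_pose_table(p)
    assert np.linalg.norm(frames[0].coords["C"]) == pytest.approx(0.30)


def test_undeclared_unit_is_never_guessed(tmp_path):
    p = tmp_path / "poses.csv"
    p.write_text("frame,role,x,y,z\n0,C,3.0,0,0\n")
    with pytest.raises(DataFormatError, match="never guessed"):
        read_pose_table(p)


def test_xyz_trajectory_with_role_mapping(tmp_path):
    p = tmp_path / "traj.xyz"
    # two frames, three atoms each, angstrom coordinates
    p.write_text(
        "3\nframe 0\nFe 0 0 -1.63\nO 0 0 0\nC 0 0 3.0\n"
        "3\nframe 1\nFe 0 0 -1.63\nO 0 0 0\nC 0 0 4.0\n"
    )
    frames = read_xyz_trajectory(p, {0: "Fe", 1: "O_ferryl", 2: "C"}, unit="angstrom")
    assert len(frames) == 2
    assert np.linalg.norm(frames[0].coords["C"]) == pytest.approx(0.30)
    assert np.linalg.norm(frames[1].coords["C"]) == pytest.approx(0.40)
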