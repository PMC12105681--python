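import numpy as np
import pytest

import clusterpdf as cp
from clusterpdf.exceptions import PairingError, ValidationError


def rotate_about_axis(model, axis, alpha_deg):
    """Rigidly rotate a whole model about the principal axis (test helper)."""
    n = axis.direction
    alpha = np.radians(alpha_deg)
    c, s = np.cos(alpha), np.sin(alpha)
    out = []
    for p in model.positions:
        u = p - axis.origin
        u_par = np.dot(u, n) * n
        u_perp = u - u_par
        out.append(axis.origin + u_par + c * u_perp + s * np.cross(n, u_perp))
    return model.with_positions(np.array(out))


class TestDisplacementField:
    def test_identity_gives_zero(self, toy):
        model, _ = toy
        records = cp.displacement_field(model, model)
        assert all(r.magnitude == 0.0 for r in records)

    def test_uniform_translation(self, toy):
        model, _ = toy
        moved = model.with_positions(model.positions + np.array([0.3, 0.0, 0.0]))
        records = cp.displacement_field(model, moved)
        for r in records:
            assert r.magnitude == pytest.approx(0.3)
            assert np.allclose(r.vector, [0.3, 0.0, 0.0])

    def test_injected_shifts_recovered(self, toy):
        model, _ = toy
        rng = np.random.default_rng(0)
        shifts = rng.normal(0, 0.2, (len(model), 3))
        moved = model.with_positions(model.positions + shifts)
        records = cp.displacement_field(model, moved)
        expected = np.linalg.norm(shifts, axis=1)
        got = np.array([r.magnitude for r in records])
        assert np.max(np.abs(got - expected)) < 1e-12

    def test_antisymmetry(self, toy):
        model, _ = toy
        moved = model.with_positions(model.positions + 0.1)
        fwd = cp.displacement_field(model, moved)
        back = cp.displacement_field(moved, model)
        for a, b in zip(fwd, back):
            assert np.allclose(a.vector, -b.vector)

    def test_label_mismatch_raises(self, toy, two_atom_model):
        model, _ = toy
        with pytest.raises(PairingError):
            cp.displacement_field(model, two_atom_model)


class TestPrincipalAxis:
    def test_elongated_cluster_axis_near_z(self, toy):
        model, _ = toy
        axis = cp.principal_axis(model)
        assert abs(np.dot(axis.direction, [0, 0, 1])) > 0.98

    def test_equivariance_under_rotation(self, toy):
        from scipy.spatial.transform import Rotation

        model, _ = toy
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        rotated = model.with_positions(model.positions @ R.T)
        a = cp.principal_axis(model).direction
        b = cp.principal_axis(rotated).direction
        assert min(np.linalg.norm(R @ a - b), np.linalg.norm(R @ a + b)) < 1e-9

    def test_degenerate_shape_warns(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-3, 3, (40, 3))  # isotropic blob
        sites = [cp.AtomSite("C", p, label=f"C{i + 1}") for i, p in enumerate(pos)]
        with pytest.warns(UserWarning):
            cp.principal_axis(cp.ClusterModel(sites), degeneracy_ratio=5.0)

    def test_too_few_atoms_raise(self, two_atom_model):
        with pytest.raises(ValidationError):
            cp.principal_axis(two_atom_model)


class TestRotationAngles:
    @pytest.mark.parametrize("alpha", [-10.0, 10.0, 20.0])
    def test_rigid_rotation_recovered(self, toy, alpha):
        model, _ = toy
        axis = cp.principal_axis(model)
        rotated = rotate_about_axis(model, axis, alpha)
        angles = cp.rotation_angles(model, rotated, axis)
        off_axis = [a for a in angles.values() if np.isfinite(a)]
        assert len(off_axis) >= 16
        assert np.allclose(off_axis, alpha, atol=1e-9)

    def test_chord_length_identity(self, toy):
        # |displacement| of an atom rotated by alpha at radius rho is
        # 2 rho sin(alpha/2): cross-checks displacement_field
        model, _ = toy
        axis = cp.principal_axis(model)
        alpha = 14.0
        rotated = rotate_about_axis(model, axis, alpha)
        records = cp.analyze_distortion(model, rotated, axis=axis)
        for rec in records:
            if rec.on_axis:
                continue
            expected = 2 * rec.radial_distance * np.sin(np.radians(alpha) / 2)
            assert rec.magnitude == pytest.approx(expected, abs=1e-9)

    def test_identity_gives_zero_angles(self, toy):
        model, _ = toy
        axis = cp.principal_axis(model)
        angles = cp.rotation_angles(model, model, axis)
        finite = [a for a in angles.values() if np.isfinite(a)]
        assert np.allclose(finite, 0.0)

    def test_on_axis_atom_flagged(self):
        sites = [
            cp.AtomSite("Ag", np.array([2.0, 0.0, z]), label=f"Ag{z + 3:.0f}")
            for z in (-2.0, -1.0, 0.0, 1.0)
        ] + [cp.AtomSite("Cl", np.array([0.0, 0.0, 3.0]), label="Cl1")]
        model = cp.ClusterModel(sites)
        axis = cp.PrincipalAxis(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        angles = cp.rotation_angles(model, model, axis)
        assert not np.isfinite(angles["Cl1"])


class TestChannelStats:
    def test_two_groups_with_opposite_rotation(self, toy):
        model, channel_map = toy
        axis = cp.principal_axis(model)
        # rotate channels 1+2 by +5 and channels 3+4 by -5
        group_of = {lab: ("pos" if ch in ("ch1", "ch2") else "neg" if ch.startswith("ch") else "cap")
                    for lab, ch in channel_map.items()}
        pos = model.positions.copy()
        n = axis.direction
        for k, lab in enumerate(model.labels):
            if group_of[lab] == "cap":
                continue
            sign = 1.0 if group_of[lab] == "pos" else -1.0
            a = np.radians(5.0) * sign
            u = pos[k] - axis.origin
            u_par = np.dot(u, n) * n
            u_perp = u - u_par
            pos[k] = axis.origin + u_par + np.cos(a) * u_perp + np.sin(a) * np.cross(n, u_perp)
        rotated = model.with_positions(pos)
        records = cp.analyze_distortion(model, rotated, channel_map=group_of, axis=axis)
        stats = cp.channel_stats(records)
        assert stats["pos"]["mean_angle_deg"] == pytest.approx(5.0, abs=1e-9)
        assert stats["neg"]["mean_angle_deg"] == pytest.approx(-5.0, abs=1e-9)
        assert stats["pos"]["sense"] == "counterclockwise"
        assert stats["neg"]["sense"] == "clockwise"

    def test_single_group_mean_equals_global(self, toy):
        model, channel_map = toy
        axis = cp.principal_axis(model)
        rotated = rotate_about_axis(model, axis, 3.0)
        one_group = {lab: ("all" if ch != "cap" else "cap") for lab, ch in channel_map.items()}
        records = cp.analyze_distortion(model, rotated, channel_map=one_group, axis=axis)
        stats = cp.channel_stats(records)
        finite = [r.rotation_angle for r in records
                  if np.isfinite(r.rotation_angle) and r.channel == "all"]
        assert stats["all"]["mean_angle_deg"] == pytest.approx(np.mean(finite))

    def test_strand_grouping(self, toy):
        model, channel_map = toy
        strand_map = {
            lab: ("A" if ch in ("ch1", "ch2") else "B" if ch.startswith("ch") else "none")
            for lab, ch in channel_map.items()
        }
        tagged = model.apply_strand_map(strand_map)
        rotated = tagged.with_positions(tagged.positions + 0.1)
        records = cp.analyze_distortion(tagged, rotated)
        stats = cp.channel_stats(records, by="strand")
        assert stats["A"]["n_atoms"] == 8 and stats["B"]["n_atoms"] == 8
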