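"""Curvature analysis: bend/twist recovery, axes, extension, motifs."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pfgeom.curvature import (
    ProtofilamentModel,
    SubunitModel,
    curvature_profile,
    decompose_bend_twist,
    extend_protofilament,
    filament_axis,
    helix_rotation,
    motif_rmsd,
    subunit_rotation,
    swing_twist_matrices,
)
from pfgeom.structio import Selection
from pfgeom.superpose import AxisAngle, RigidTransform, axis_angle
from pfgeom.synthetic import FilamentSpec, build_filament


def apply_global(structure, R, t):
    out = structure.copy()
    for atom in out.atoms():
        atom.position = R @ atom.position + t
    return out


class TestDecomposeBendTwist:
    def test_pure_twist(self):
        R = Rotation.from_euler("z", 20, degrees=True).as_matrix()
        aa = axis_angle(RigidTransform(R, np.zeros(3)))
        bend, twist = decompose_bend_twist(aa, np.array([0.0, 0.0, 1.0]))
        assert twist == pytest.approx(20.0, abs=1e-9)
        assert bend == pytest.approx(0.0, abs=1e-9)

    def test_pure_bend(self):
        R = Rotation.from_euler("x", 20, degrees=True).as_matrix()
        aa = axis_angle(RigidTransform(R, np.zeros(3)))
        bend, twist = decompose_bend_twist(aa, np.array([0.0, 0.0, 1.0]))
        assert bend == pytest.approx(20.0, abs=1e-9)
        assert twist == pytest.approx(0.0, abs=1e-9)

    def test_constructed_swing_twist_recovered(self, rng):
        """Compose a known bend about a perpendicular axis with a known
        twist; the decomposition must return exactly those inputs."""
        for _ in range(50):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            perp = np.cross(axis, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
            bend_in = float(rng.uniform(0.5, 170.0))
            twist_in = float(rng.uniform(0.5, 170.0))
            R = (Rotation.from_rotvec(np.deg2rad(bend_in) * perp)
                 * Rotation.from_rotvec(np.deg2rad(twist_in) * axis)).as_matrix()
            aa = axis_angle(RigidTransform(R, np.zeros(3)))
            bend, twist = decompose_bend_twist(aa, axis)
            assert bend == pytest.approx(bend_in, abs=1e-8)
            assert twist == pytest.approx(twist_in, abs=1e-8)

    def test_recomposition_identity(self, rng):
        for _ in range(50):
            R = Rotation.random(random_state=np.random.RandomState(
                rng.integers(0, 2**31 - 1))).as_matrix()
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            S, T = swing_twist_matrices(R, axis)
            np.testing.assert_allclose(S @ T, R, atol=1e-9)
            # twist factor really is about the reference axis
            np.testing.assert_allclose(T @ axis, axis, atol=1e-9)

    def test_components_bounded_by_total(self, rng):
        for _ in range(50):
            R = Rotation.random(random_state=np.random.RandomState(
                rng.integers(0, 2**31 - 1))).as_matrix()
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            aa = axis_angle(RigidTransform(R, np.zeros(3)))
            bend, twist = decompose_bend_twist(aa, axis)
            assert bend <= aa.angle + 1e-9
            assert twist <= aa.angle + 1e-9


class TestFilamentAxis:
    def test_straight_filament_on_z(self):
        st, _ = build_filament(FilamentSpec(n_subunits=4, seed=8))
        model = ProtofilamentModel.from_chains(list("ABCD"))
        axis = filament_axis(st, model)
        np.testing.assert_allclose(axis, [0.0, 0.0, 1.0], atol=1e-9)

    def test_matches_svd_oracle(self, rng):
        st, _ = build_filament(FilamentSpec(
            n_subunits=5, bend_per_interface=11.0, twist_per_interface=4.0,
            seed=13))
        model = ProtofilamentModel.from_chains(list("ABCDE"),
                                               roles=["pseudo"] * 5)
        axis = filament_axis(st, model)
        cents = np.array([
            np.mean([a.position for r in st.chain(c).residues for a in r.atoms],
                    axis=0) for c in "ABCDE"])
        _, _, Vt = np.linalg.svd(cents - cents.mean(axis=0))
        assert abs(axis @ Vt[0]) == pytest.approx(1.0, abs=1e-12)

    def test_equivariance_under_global_rotation(self, rng):
        st, _ = build_filament(FilamentSpec(n_subunits=4,
                                            bend_per_interface=9.0, seed=3))
        model = ProtofilamentModel.from_chains(list("ABCD"))
        R = Rotation.from_euler("xyz", [31, -47, 12], degrees=True).as_matrix()
        moved = apply_global(st, R, np.array([5.0, -3.0, 8.0]))
        np.testing.assert_allclose(
            filament_axis(moved, model), R @ filament_axis(st, model), atol=1e-9)


class TestCurvatureRecovery:
    def test_subunit_vs_itself_is_zero(self):
        st, _ = build_filament(FilamentSpec(n_subunits=2, seed=1))
        su = SubunitModel("alpha", "A")
        rep = subunit_rotation(st, su, su)
        assert rep.total_angle == pytest.approx(0.0, abs=1e-9)

    def test_straight_filament_all_zero(self):
        st, _ = build_filament(FilamentSpec(n_subunits=4, seed=6))
        reps = curvature_profile(st, ProtofilamentModel.from_chains(list("ABCD")))
        for r in reps:
            assert r.total_angle < 1e-8

    def test_programmed_angles_recovered_exactly(self, curved_filament):
        st, truth = curved_filament
        reps = curvature_profile(st, ProtofilamentModel.from_chains(list("ABCD")))
        assert len(reps) == 3
        for rep, (bend, twist, rise) in zip(reps, truth):
            assert rep.bend_component == pytest.approx(bend, abs=1e-6)
            assert rep.twist_component == pytest.approx(twist, abs=1e-6)
            assert rep.rise == pytest.approx(rise, abs=1e-6)
            assert rep.rmsd < 1e-9

    def test_intra_inter_labels(self, curved_filament):
        st, _ = curved_filament
        reps = curvature_profile(st, ProtofilamentModel.from_chains(list("ABCD")))
        assert [r.pair_label.split()[-1] for r in reps] == ["intra", "inter", "intra"]

    def test_frame_invariance(self, curved_filament, rng):
        st, _ = curved_filament
        model = ProtofilamentModel.from_chains(list("ABCD"))
        base = curvature_profile(st, model)
        R = Rotation.random(random_state=np.random.RandomState(77)).as_matrix()
        moved = apply_global(st, R, rng.normal(scale=20, size=3))
        other = curvature_profile(moved, model)
        for a, b in zip(base, other):
            assert b.total_angle == pytest.approx(a.total_angle, abs=1e-9)
            assert b.bend_component == pytest.approx(a.bend_component, abs=1e-9)
            assert b.twist_component == pytest.approx(a.twist_component, abs=1e-9)

    def test_noise_bias_small_over_seeds(self):
        """sigma = 0.2 A coordinate noise: the mean recovered bend over
        100 seeds stays within 0.1 deg of the programmed value."""
        programmed = [15.8, 12.1, 8.0]
        model = ProtofilamentModel.from_chains(list("ABCD"))
        total = np.zeros(3)
        n_seeds = 100
        for seed in range(n_seeds):
            st, _ = build_filament(FilamentSpec(
                n_subunits=4, atoms_per_subunit=120,
                bend_per_interface=programmed, twist_per_interface=2.0,
                noise_sigma=0.2, seed=seed))
            reps = curvature_profile(st, model, reject_factor=np.inf)
            total += [r.bend_component for r in reps]
        mean = total / n_seeds
        np.testing.assert_allclose(mean, programmed, atol=0.1)

    def test_alternating_role_validation(self):
        with pytest.raises(ValueError, match="alternate"):
            ProtofilamentModel.from_chains(["A", "B"], roles=["alpha", "alpha"])


class TestExtendProtofilament:
    def test_straight_extension_collinear(self):
        st, _ = build_filament(FilamentSpec(n_subunits=4, seed=4))
        model = ProtofilamentModel.from_chains(list("ABCD"))
        ext = extend_protofilament(st, model, 5)
        assert len(ext.chains) == 4 + 10
        cents = np.array([
            np.mean([a.position for r in c.residues for a in r.atoms], axis=0)
            for c in ext.chains])
        s = np.linalg.svd(cents - cents.mean(axis=0), compute_uv=False)
        assert s[1] < 1e-6

    def test_curved_extension_preserves_interface_angles(self):
        """Uniform programmed curvature: the appended dimers continue the
        arc, every re-measured interface equal to the original one."""
        st, _ = build_filament(FilamentSpec(
            n_subunits=4, atoms_per_subunit=100,
            bend_per_interface=12.0, twist_per_interface=2.0, seed=5))
        model = ProtofilamentModel.from_chains(list("ABCD"))
        original = curvature_profile(st, model)
        ext = extend_protofilament(st, model, 2)
        ids = [c.chain_id for c in ext.chains]
        grown = ProtofilamentModel.from_chains(ids[2:])
        reps = curvature_profile(ext, grown)
        assert len(reps) == 5
        for rep in reps:
            assert rep.total_angle == pytest.approx(original[1].total_angle,
                                                    abs=1e-6)

    def test_bad_copy_count(self, curved_filament):
        st, _ = curved_filament
        model = ProtofilamentModel.from_chains(list("ABCD"))
        with pytest.raises(ValueError):
            extend_protofilament(st, model, 0)


class TestMotifComparison:
    def test_structure_vs_itself(self, curved_filament):
        st, _ = curved_filament
        frame = (Selection("A", [(1, 60)]), Selection("A", [(1, 60)]))
        motif = (Selection("A", [(61, 80)]), Selection("A", [(61, 80)]))
        mc = motif_rmsd(st, st, frame, motif)
        assert mc.rmsd == pytest.approx(0.0, abs=1e-9)
        assert mc.max_displacement == pytest.approx(0.0, abs=1e-9)

    def test_displaced_motif_detected(self, curved_filament):
        st, _ = curved_filament
        other = st.copy()
        shift = np.array([0.0, 0.0, 4.0])
        for res in other.chain("A").residues:
            if 61 <= res.number <= 80:
                for a in res.atoms:
                    a.position = a.position + shift
        frame = (Selection("A", [(1, 60)]), Selection("A", [(1, 60)]))
        motif = (Selection("A", [(61, 80)]), Selection("A", [(61, 80)]))
        mc = motif_rmsd(st, other, frame, motif)
        assert mc.rmsd == pytest.approx(4.0, abs=1e-6)
        assert mc.max_displacement == pytest.approx(4.0, abs=1e-6)
        assert mc.max_displacement >= max(d for _, d in mc.per_residue_displacements) - 1e-12

    def test_motif_displacement_survives_global_motion(self, curved_filament, rng):
        st, _ = curved_filament
        other = st.copy()
        for res in other.chain("A").residues:
            if 61 <= res.number <= 80:
                for a in res.atoms:
                    a.position = a.position + np.array([2.5, 0.0, 0.0])
        R = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        other = apply_global(other, R, rng.normal(scale=30, size=3))
        frame = (Selection("A", [(1, 60)]), Selection("A", [(1, 60)]))
        motif = (Selection("A", [(61, 80)]), Selection("A", [(61, 80)]))
        mc = motif_rmsd(st, other, frame, motif)
        assert mc.rmsd == pytest.approx(2.5, abs=1e-6)


class TestHelixRotation:
    def test_identical_structures_zero(self, curved_filament):
        st, _ = curved_filament
        frame = (Selection("A", [(1, 40)]), Selection("A", [(1, 40)]))
        hel = (Selection("A", [(41, 70)]), Selection("A", [(41, 70)]))
        assert helix_rotation(st, st, frame, hel) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_26_degree_rotation(self, curved_filament):
        """Rotate the helix group by 26 deg about its own centroid inside a
        fixed frame; the measured rotation must be exactly 26 deg."""
        st, _ = curved_filament
        other = st.copy()
        helix_atoms = [a for res in other.chain("A").residues
                       if 41 <= res.number <= 70 for a in res.atoms]
        centroid = np.mean([a.position for a in helix_atoms], axis=0)
        R = Rotation.from_euler("y", 26, degrees=True).as_matrix()
        for a in helix_atoms:
            a.position = R @ (a.position - centroid) + centroid
        frame = (Selection("A", [(1, 40)]), Selection("A", [(1, 40)]))
        hel = (Selection("A", [(41, 70)]), Selection("A", [(41, 70)]))
        assert helix_rotation(st, other, frame, hel) == pytest.approx(26.0, abs=1e-6)
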