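"""Toy docking, pose geometry, binding propensity and contact annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ensemblebind.errors import AnalysisError
from ensemblebind.io_formats import Pose, PoseSet, Structure, Trajectory
from ensemblebind.propensity import (
    DockParams,
    Pocket,
    annotate_contacts,
    binding_propensity,
    group_poses,
    pocket_overlap,
    pose_distance,
    score_pose,
    toy_dock,
)
from ensemblebind.synthetic import TrajectorySpec, make_ligand, make_pose_sets, make_trajectory


def cage_structure(atom_factory, radius=4.0, n=14):
    """Protein-like cage of CA atoms on a sphere: a spherical cavity."""
    golden = np.pi * (3 - np.sqrt(5))
    atoms = []
    for k in range(n):
        z = 1 - 2 * (k + 0.5) / n
        r = np.sqrt(1 - z * z)
        phi = k * golden
        xyz = radius * np.array([r * np.cos(phi), r * np.sin(phi), z])
        atoms.append(atom_factory(k + 1, "CA", "C", k + 1, xyz=tuple(xyz)))
    return Structure(atoms)


@pytest.fixture
def single_atom_ligand(atom_factory):
    return Structure([atom_factory(1, "C1", "C", 1, resname="LIG", chain="L", hetero=True)])


class TestToyDock:
    def test_best_pose_at_cavity_center(self, atom_factory, single_atom_ligand):
        frame = cage_structure(atom_factory, radius=3.0)
        pocket = Pocket("cage", frozenset(range(1, 15)))
        ps = toy_dock(frame, single_atom_ligand, pocket, grid_step_A=1.0, n_orientations=1, seed=0)
        best = ps.poses[0].xyz.mean(axis=0)
        # brute-force fine-grid oracle over the cavity interior
        grid = np.stack(
            np.meshgrid(*[np.arange(-2, 2.01, 0.25)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        scores = [score_pose(frame, single_atom_ligand, g[None, :]) for g in grid]
        oracle = grid[int(np.argmin(scores))]
        assert np.linalg.norm(best - oracle) <= 1.0 + 1e-9  # within the coarse grid step
        assert np.linalg.norm(oracle) < 0.3  # the cavity centre, by near-symmetry

    def test_clashing_pose_scores_worse(self, atom_factory, single_atom_ligand):
        frame = cage_structure(atom_factory)
        on_top = frame.coords()[0][None, :]  # coincides with a protein atom
        clash_free = np.zeros((1, 3))
        assert score_pose(frame, single_atom_ligand, on_top) > score_pose(
            frame, single_atom_ligand, clash_free
        )

    def test_same_seed_identical_poses(self, atom_factory, ligand):
        frame = cage_structure(atom_factory, radius=6.0)
        pocket = Pocket("cage", frozenset(range(1, 15)))
        a = toy_dock(frame, ligand, pocket, seed=42)
        b = toy_dock(frame, ligand, pocket, seed=42)
        assert [p.score for p in a.poses] == [p.score for p in b.poses]
        assert all(np.array_equal(x.xyz, y.xyz) for x, y in zip(a.poses, b.poses))

    def test_score_invariant_under_joint_rigid_motion(self, atom_factory, ligand):
        frame = cage_structure(atom_factory)
        pose = ligand.coords() * 0.3  # shrink into the cavity
        rot = Rotation.from_euler("zyx", [31, -17, 55], degrees=True).as_matrix()
        shift = np.array([3.0, -2.0, 7.0])
        moved_frame = frame.with_coords(frame.coords() @ rot.T + shift)
        s0 = score_pose(frame, ligand, pose)
        s1 = score_pose(moved_frame, ligand, pose @ rot.T + shift)
        assert s1 == pytest.approx(s0, abs=1e-9)


class TestPoseDistance:
    def _setup(self, helix):
        pocket = Pocket("p", frozenset({5, 6, 7, 8}))
        ref_pose = np.array([[0.0, 0, 8], [1.5, 0, 8], [0, 1.5, 8]])
        return pocket, ref_pose

    def test_zero_for_identical_pose(self, helix12):
        pocket, ref = self._setup(helix12)
        d = pose_distance(ref, ref, helix12, helix12, pocket)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation_is_exact(self, helix12):
        pocket, ref = self._setup(helix12)
        d = pose_distance(ref + np.array([0, 3.0, 0]), ref, helix12, helix12, pocket)
        assert d == pytest.approx(3.0, abs=1e-9)

    def test_matches_independent_superposition_oracle(self, helix12):
        pocket, ref = self._setup(helix12)
        rng = np.random.default_rng(13)
        rot = Rotation.random(random_state=3).as_matrix()
        shift = rng.normal(scale=5.0, size=3)
        frame_b = helix12.with_coords(helix12.coords() @ rot.T + shift)
        offset = np.array([0.7, -0.4, 1.1])
        pose_b = (ref + offset) @ rot.T + shift
        got = pose_distance(pose_b, ref, frame_b, helix12, pocket)
        # oracle: align pocket backbone with scipy, then plain RMSD
        sel = pocket.backbone_indices(helix12)
        r_or, _ = Rotation.align_vectors(
            helix12.coords()[sel] - helix12.coords()[sel].mean(axis=0),
            frame_b.coords()[sel] - frame_b.coords()[sel].mean(axis=0),
        )
        moved = r_or.as_matrix() @ (pose_b - frame_b.coords()[sel].mean(axis=0)).T
        moved = moved.T + helix12.coords()[sel].mean(axis=0)
        oracle = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
        assert got == pytest.approx(oracle, abs=1e-3)
        # the rigid motion cancels, leaving exactly the planted offset
        assert got == pytest.approx(np.linalg.norm(offset), abs=1e-6)


class TestGroupsAndPropensity:
    @pytest.fixture
    def traj_and_ref(self, helix12):
        traj = Trajectory(topology=helix12, xyz=np.repeat(helix12.coords()[None], 6, axis=0))
        ref = np.array([[0.0, 0, 8], [1.5, 0, 8], [0, 1.5, 8], [1.5, 1.5, 8]])
        pocket = Pocket("p", frozenset({5, 6, 7, 8}))
        lig = make_ligand(n_tail=0)
        lig = Structure(lig.atoms[:4])
        return traj, ref, pocket, lig

    def test_all_identical_poses_one_group(self, traj_and_ref):
        traj, ref, pocket, lig = traj_and_ref
        poses = [Pose(k + 1, k + 1, ref.copy(), -7.0) for k in range(6)]
        ps = PoseSet(ligand_topology=lig, poses=poses)
        groups = group_poses(ps, ref, traj, traj.xyz[0], pocket, bin_width_A=2.0)
        assert len(groups) == 1
        assert groups[0].n == 6
        assert groups[0].mean_score == pytest.approx(-7.0)

    def test_bimodal_distances_split_into_two_groups(self, traj_and_ref):
        traj, ref, pocket, lig = traj_and_ref
        near = [Pose(k + 1, k + 1, ref + [0.5, 0, 0], -8.0 - k) for k in range(4)]
        far = [Pose(k + 5, k + 5, ref + [6.0, 0, 0], -3.0) for k in range(2)]
        ps = PoseSet(ligand_topology=lig, poses=near + far)
        groups = group_poses(ps, ref, traj, traj.xyz[0], pocket, bin_width_A=2.0)
        assert [g.n for g in groups] == [4, 2]
        assert groups[0].mean_score == pytest.approx(np.mean([-8, -9, -10, -11]))
        assert groups[1].mean_distance_A == pytest.approx(6.0, abs=1e-9)
        assert sum(g.n for g in groups) == len(ps.best_pose_per_frame())

    def test_best_pose_per_frame_uses_lowest_score(self, traj_and_ref):
        traj, ref, pocket, lig = traj_and_ref
        poses = [
            Pose(1, 1, ref + [6.0, 0, 0], -2.0),
            Pose(1, 2, ref.copy(), -9.0),  # better score, near reference
        ]
        ps = PoseSet(ligand_topology=lig, poses=poses)
        res = binding_propensity(ps, ref, traj, traj.xyz[0], pocket, distance_cutoff_A=2.0)
        assert res.propensity == 1.0

    def test_extreme_fractions(self, traj_and_ref):
        traj, ref, pocket, lig = traj_and_ref
        ps_all, _ = make_pose_sets(traj, lig, ref, bound_fraction=1.0, seed=1)
        ps_none, _ = make_pose_sets(traj, lig, ref, bound_fraction=0.0, seed=1)
        hit = binding_propensity(ps_all, ref, traj, traj.xyz[0], pocket, score_threshold=-6.0)
        miss = binding_propensity(ps_none, ref, traj, traj.xyz[0], pocket, score_threshold=-6.0)
        assert hit.propensity == 1.0
        assert miss.propensity == 0.0

    def test_planted_fraction_recovered_exactly(self, helix12):
        traj, _ = make_trajectory(TrajectorySpec(n_residues=12, sigma_A=0.2, n_frames=400, seed=17))
        pocket = Pocket("p", frozenset({5, 6, 7, 8}))
        lig = make_ligand()
        ref = lig.coords() - lig.coords().mean(axis=0) + pocket.centroid(traj.frame(1))
        ps, truth = make_pose_sets(
            traj, lig, ref, bound_fraction=0.30,
            pocket=pocket, reference_frame_xyz=traj.xyz[0], seed=23,
        )
        res = binding_propensity(
            ps, ref, traj, traj.xyz[0], pocket, distance_cutoff_A=2.0, score_threshold=-6.0
        )
        assert res.propensity == pytest.approx(truth.bound_fraction_realized, abs=1e-12)
        assert abs(res.propensity - 0.30) < 2 * np.sqrt(0.3 * 0.7 / 400) + 1e-12

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        c1=st.floats(min_value=0.5, max_value=8.0),
        c2=st.floats(min_value=0.0, max_value=8.0),
        thr_step=st.floats(min_value=0.0, max_value=5.0),
    )
    def test_propensity_monotone_in_cutoffs(self, c1, c2, thr_step):
        traj, _ = make_trajectory(TrajectorySpec(n_residues=12, sigma_A=0.2, n_frames=60, seed=29))
        pocket = Pocket("p", frozenset({5, 6, 7, 8}))
        lig = make_ligand()
        ref = lig.coords() - lig.coords().mean(axis=0) + pocket.centroid(traj.frame(1))
        ps, _ = make_pose_sets(
            traj, lig, ref, bound_fraction=0.5,
            pocket=pocket, reference_frame_xyz=traj.xyz[0], seed=31,
        )
        lo, hi = sorted((c1, c2))
        p_lo = binding_propensity(ps, ref, traj, traj.xyz[0], pocket, lo, -6.0).propensity
        p_hi = binding_propensity(ps, ref, traj, traj.xyz[0], pocket, hi, -6.0).propensity
        assert p_lo <= p_hi
        p_loose = binding_propensity(ps, ref, traj, traj.xyz[0], pocket, hi, -6.0 + thr_step).propensity
        assert p_hi <= p_loose


class TestContacts:
    def _frame_with_backbone_pair(self, atom_factory, acceptor_distance, angle_deg):
        """Backbone N (donor, antecedent CA) plus a ligand O acceptor placed at
        the requested donor distance/angle."""
        n_pos = np.zeros(3)
        ca_pos = np.array([1.47, 0.0, 0.0])
        theta = np.radians(angle_deg)
        acc = acceptor_distance * np.array([np.cos(theta), np.sin(theta), 0.0])
        frame = Structure(
            [
                atom_factory(1, "N", "N", 1, xyz=tuple(n_pos)),
                atom_factory(2, "CA", "C", 1, xyz=tuple(ca_pos)),
                atom_factory(3, "C", "C", 1, xyz=(2.0, 1.2, 0.0)),
            ]
        )
        lig = Structure([atom_factory(1, "O1", "O", 1, resname="LIG", chain="L", hetero=True)])
        return frame, lig, acc[None, :]

    def test_hbond_inside_criteria(self, atom_factory):
        frame, lig, pose = self._frame_with_backbone_pair(atom_factory, 2.9, 160.0)
        report = annotate_contacts(frame, lig, pose)
        hb = report.of_kind("hbond")
        assert len(hb) == 1
        assert hb[0].distance_A == pytest.approx(2.9, abs=1e-9)
        assert hb[0].angle_deg == pytest.approx(160.0, abs=1e-6)

    def test_no_hbond_beyond_distance(self, atom_factory):
        frame, lig, pose = self._frame_with_backbone_pair(atom_factory, 4.0, 160.0)
        assert annotate_contacts(frame, lig, pose).of_kind("hbond") == []

    def test_no_hbond_below_angle(self, atom_factory):
        frame, lig, pose = self._frame_with_backbone_pair(atom_factory, 2.9, 60.0)
        assert annotate_contacts(frame, lig, pose).of_kind("hbond") == []

    def test_pipi_between_rings(self, atom_factory, ligand):
        # PHE side-chain ring 4 A above the ligand's benzene ring
        ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        atoms = []
        for k, name in enumerate(ring_names):
            ang = np.radians(60.0 * k)
            atoms.append(
                atom_factory(k + 1, name, "C", 7, resname="PHE",
                             xyz=(1.39 * np.cos(ang), 1.39 * np.sin(ang), 4.0))
            )
        frame = Structure(atoms)
        report = annotate_contacts(frame, ligand, ligand.coords())
        pp = report.of_kind("pipi")
        assert len(pp) == 1
        assert pp[0].protein_residue == (7, "PHE")
        assert pp[0].distance_A == pytest.approx(4.0, abs=1e-9)

    def test_matches_exhaustive_pair_enumeration(self, helix12, ligand):
        # oracle: explicit loops over every polar pair with the same geometry rules
        pose = ligand.coords() - ligand.coords().mean(axis=0) + helix12.coords().mean(axis=0)
        report = annotate_contacts(helix12, ligand, pose)
        got = {(c.ligand_atoms[0], c.protein_residue[0]) for c in report.of_kind("hbond")}
        expect = set()
        pc = helix12.coords()
        for li, la in enumerate(ligand.atoms):
            if la.element not in ("N", "O", "S"):
                continue
            for pi, pa in enumerate(helix12.atoms):
                if pa.name not in ("N", "O"):
                    continue
                d = np.linalg.norm(pose[li] - pc[pi])
                if d > 3.5:
                    continue
                if pa.name == "N":  # protein donor: angle at N over bonded same-residue atoms
                    ants = [
                        j for j in range(helix12.n_atoms)
                        if j != pi
                        and helix12.atoms[j].residue_id == pa.residue_id
                        and np.linalg.norm(pc[j] - pc[pi]) <= 1.8
                    ]
                    vecs = [(pc[j] - pc[pi], pose[li] - pc[pi]) for j in ants]
                else:  # protein acceptor: angle at the ligand donor atom
                    ants = [
                        j for j in range(ligand.n_atoms)
                        if j != li and np.linalg.norm(pose[j] - pose[li]) <= 1.8
                    ]
                    vecs = [(pose[j] - pose[li], pc[pi] - pose[li]) for j in ants]
                if not ants:
                    ok = True
                else:
                    angs = [
                        np.degrees(np.arccos(np.clip(
                            np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
                        for v1, v2 in vecs
                    ]
                    ok = max(angs) >= 120.0
                if ok:
                    expect.add((la.name, pa.residue_id))
        assert got == expect


class TestPocketOverlap:
    def test_identical_and_disjoint(self):
        a = Pocket("a", frozenset(range(1, 11)))
        assert pocket_overlap(a, a)[1] == 1.0
        b = Pocket("b", frozenset(range(20, 30)))
        assert pocket_overlap(a, b) == (set(), 0.0)

    def test_partial_overlap_arithmetic(self):
        a = Pocket("a", frozenset(range(1, 11)))
        b = Pocket("b", frozenset(range(6, 16)))
        shared, jac = pocket_overlap(a, b)
        assert shared == {6, 7, 8, 9, 10}
        assert jac == pytest.approx(5 / 15)
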