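"""Trajectory stability analytics: superposition, RMSD/Rg/RMSF, H-bonds,
PCA and the free-energy landscape."""

import numpy as np
import pytest

from funnelscreen.datatypes import Trajectory, make_atom_table
from funnelscreen.synthio import RigidMotion, TrajSimSpec, gen_trajectory
from funnelscreen.trajstab import (
    KB_KCAL,
    HBondCriteria,
    binding_site_selection,
    free_energy_landscape,
    hbond_stats,
    kabsch_superpose,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    select_atoms,
    trajectory_pca,
)

from conftest import PEPTIDE_COORDS, PEPTIDE_TEMPLATE, rigid_motion_schedule


def _rotation(axis, theta):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _traj_from_coords(coords, masses=None, names=None):
    n = coords.shape[1]
    masses = masses if masses is not None else [12.011] * n
    names = names or [f"C{i}" for i in range(n)]
    records = [(i + 1, "GLY", names[i], "C", True, masses[i]) for i in range(n)]
    return Trajectory(coords=coords, atoms=make_atom_table(records))


class TestKabsch:
    def test_identity_on_identical_coordinates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2, (10, 3))
        R, t, rmsd = kabsch_superpose(x, x)
        assert rmsd < 1e-12
        assert np.allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_motion_fully_removed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2, (12, 3))
        moved = x @ _rotation([0, 0, 1], np.pi / 2).T + [5.0, -3.0, 2.0]
        *_, rmsd = kabsch_superpose(moved, x)
        assert rmsd < 1e-10

    def test_matches_brute_force_rotation_search(self):
        from oracles import brute_force_fitted_rmsd

        x = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]])
        y = x.copy()
        y[3] += [0.6, -0.8, 0.0]  # displace one atom by 1 Å
        *_, rmsd = kabsch_superpose(x @ _rotation([1, 1, 0], 0.7).T + 2.0, y)
        assert rmsd == pytest.approx(brute_force_fitted_rmsd(x, y), abs=1e-4)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line + 1.0)

    def test_reflection_excluded(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (8, 3))
        mirrored = x * [1.0, 1.0, -1.0]
        R, *_ = kabsch_superpose(mirrored, x)
        assert np.linalg.det(R) == pytest.approx(1.0)


class TestRmsdSeries:
    def test_first_frame_zero_and_rigid_motion_removed(self):
        spec = TrajSimSpec(
            n_frames=25, atom_template=PEPTIDE_TEMPLATE,
            reference_coords=PEPTIDE_COORDS, fluct_sd=0.0,
            rigid_motion=rigid_motion_schedule(25, seed=3), seed=0,
        )
        traj, _ = gen_trajectory(spec)
        series = rmsd_series(traj)
        assert np.allclose(series, 0.0, atol=1e-8)

    def test_series_matches_direct_recomputation(self, peptide_traj):
        traj, _ = peptide_traj
        fit = select_atoms(traj, "protein and backbone").indices
        series = rmsd_series(traj)
        for f in (0, 17, 63):
            R, t, _ = kabsch_superpose(traj.coords[f], traj.coords[0], fit)
            moved = traj.coords[f][fit] @ R.T + t
            direct = np.sqrt(np.mean(np.sum((moved - traj.coords[0][fit]) ** 2, axis=1)))
            assert series[f] == pytest.approx(direct, abs=1e-10)

    def test_measure_selection_differs_from_fit(self, peptide_traj):
        traj, _ = peptide_traj
        lig = rmsd_series(traj, measure_selection="ligand")
        back = rmsd_series(traj)
        assert lig.shape == back.shape
        assert not np.allclose(lig, back)


class TestRg:
    def test_two_unit_masses_two_angstroms_apart(self):
        coords = np.tile(np.array([[[0.0, 0, 0], [2.0, 0, 0]]]), (4, 1, 1))
        traj = _traj_from_coords(coords, masses=[1.0, 1.0])
        assert np.all(radius_of_gyration(traj) == 1.0)

    def test_translation_invariance(self, peptide_traj):
        traj, _ = peptide_traj
        rg = radius_of_gyration(traj)
        shifted = Trajectory(traj.coords + 7.5, traj.atoms)
        assert np.allclose(radius_of_gyration(shifted), rg, atol=1e-10)

    def test_five_atom_hand_computation(self):
        coords = np.array([[[0.0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3], [1, 1, 1]]])
        masses = [1.0, 2.0, 3.0, 4.0, 5.0]
        traj = _traj_from_coords(coords, masses=masses)
        w = np.array(masses)
        com = (coords[0] * w[:, None]).sum(axis=0) / w.sum()
        expect = np.sqrt((w * ((coords[0] - com) ** 2).sum(axis=1)).sum() / w.sum())
        assert radius_of_gyration(traj)[0] == pytest.approx(expect, abs=1e-10)
        unweighted = radius_of_gyration(traj, mass_weighted=False)[0]
        com_u = coords[0].mean(axis=0)
        expect_u = np.sqrt(((coords[0] - com_u) ** 2).sum(axis=1).mean())
        assert unweighted == pytest.approx(expect_u, abs=1e-10)

    def test_rg_invariant_under_generator_rotation(self):
        motion = RigidMotion(rotation_angles=np.linspace(0.0, 2.0, 12))
        spec = TrajSimSpec(
            n_frames=12, atom_template=PEPTIDE_TEMPLATE,
            reference_coords=PEPTIDE_COORDS, fluct_sd=0.0,
            rigid_motion=motion, seed=0,
        )
        traj, _ = gen_trajectory(spec)
        rg = radius_of_gyration(traj)
        assert np.allclose(rg, rg[0], atol=1e-10)


class TestRmsf:
    def test_static_trajectory_all_zero(self, static_traj):
        traj, _ = static_traj
        per_atom, per_res = rmsf(traj)
        assert np.allclose(per_atom, 0.0, atol=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in per_res.values())

    def test_isotropic_gaussian_matches_sigma_sqrt3(self):
        rng = np.random.default_rng(0)
        n_atoms, sigma = 200, 0.5
        base = rng.normal(0, 5, (n_atoms, 3))
        coords = base[None] + rng.normal(0, sigma, (5000, n_atoms, 3))
        traj = _traj_from_coords(coords)
        per_atom, _ = rmsf(traj)
        assert np.mean(per_atom) == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_rigid_rotation_removed_by_fitting(self):
        rng = np.random.default_rng(1)
        n_atoms, sigma = 60, 0.3
        base = rng.normal(0, 5, (n_atoms, 3))
        noise = rng.normal(0, sigma, (400, n_atoms, 3))
        plain = _traj_from_coords(base[None] + noise)
        centroid = base.mean(axis=0)
        rotated = np.empty_like(plain.coords)
        angles = rng.uniform(-0.4, 0.4, 400)
        for f in range(400):
            R = _rotation([0.2, 0.9, -0.1], angles[f])
            rotated[f] = (plain.coords[f] - centroid) @ R.T + centroid + rng.normal(0, 2, 3)
        a, _ = rmsf(plain)
        b, _ = rmsf(_traj_from_coords(rotated))
        assert np.mean(b) == pytest.approx(np.mean(a), rel=0.02)

    def test_single_frame_rejected(self):
        traj = _traj_from_coords(np.zeros((1, 4, 3)))
        with pytest.raises(ValueError):
            rmsf(traj)


class TestHbonds:
    def test_scheduled_occupancy_and_cutoff_filtering(self, peptide_traj):
        traj, _ = peptide_traj
        headline, full, counts = hbond_stats(traj, [(5, 6, 11)])
        assert full[0].occupancy == 60.0
        assert len(headline) == 1
        assert counts.sum() == 60
        assert full[0].average_distance == pytest.approx(2.8, abs=0.05)

    def test_low_occupancy_bond_excluded_from_headline_only(self):
        spec = TrajSimSpec(
            n_frames=100, atom_template=PEPTIDE_TEMPLATE,
            reference_coords=PEPTIDE_COORDS, fluct_sd=0.03,
            hbond_schedule=[(5, 6, 11, 0.15)], seed=2,
        )
        traj, _ = gen_trajectory(spec)
        headline, full, _ = hbond_stats(traj, [(5, 6, 11)])
        assert full[0].occupancy == pytest.approx(15.0)
        assert headline == []

    def test_boundary_geometry_is_inclusive(self):
        """A bond sitting exactly at the cutoffs counts as satisfied.

        Collinear D–H···A gives an angle of exactly 180° and the acceptor is
        placed at exactly the distance cutoff from the donor; the independent
        geometric recomputation (plain dot products) agrees.
        """
        d = np.zeros(3)
        h = np.array([1.0, 0.0, 0.0])
        a = np.array([3.0, 0.0, 0.0])  # D···A exactly 3.0, angle exactly 180
        coords = np.array([[d, h, a], [d, h, a]])
        records = [
            (1, "GLY", "N", "N", True, 14.007),
            (1, "GLY", "H", "H", False, 1.008),
            (2, "LIG", "O1", "O", False, 15.999),
        ]
        traj = Trajectory(coords=coords, atoms=make_atom_table(records))
        v1, v2 = d - h, a - h
        ang = np.degrees(np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        dist = float(np.linalg.norm(d - a))
        assert ang == 180.0 and dist == 3.0
        _, full, counts = hbond_stats(
            traj, [(0, 1, 2)], HBondCriteria(distance_cutoff=3.0, angle_cutoff=180.0)
        )
        assert full[0].occupancy == 100.0
        # tightening the distance cutoff just past the boundary excludes it
        _, _, c2 = hbond_stats(
            traj, [(0, 1, 2)],
            HBondCriteria(distance_cutoff=3.0 - 1e-9, angle_cutoff=180.0),
        )
        assert c2.sum() == 0
        # a bent geometry below the angle cutoff is rejected on angle alone
        bent = coords.copy()
        bent[:, 2] = [1.0, 2.5, 0.0]  # ~2.7 A away but ~90 deg at H
        bent_traj = Trajectory(coords=bent, atoms=make_atom_table(records))
        _, _, c3 = hbond_stats(bent_traj, [(0, 1, 2)])
        assert c3.sum() == 0

    def test_per_frame_counts_are_sum_of_indicators(self, peptide_traj):
        traj, _ = peptide_traj
        _, full, counts = hbond_stats(traj, [(5, 6, 11), (0, 6, 11)])
        total = sum(b.occupancy / 100.0 * traj.n_frames for b in full)
        assert counts.sum() == pytest.approx(total)

    def test_non_hydrogen_candidate_skipped(self, peptide_traj):
        traj, _ = peptide_traj
        _, full, _ = hbond_stats(traj, [(5, 0, 11)])  # atom 0 is N, not H
        assert full == []


class TestPCA:
    def _planted_mode_traj(self, seed=0, n_atoms=10, n_frames=400):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 4, (n_atoms, 3))
        # build a collective direction orthogonal to rigid-body modes so the
        # superposition step cannot absorb it
        rigid = []
        for ax in range(3):
            m = np.zeros((n_atoms, 3))
            m[:, ax] = 1.0
            rigid.append(m.ravel())
        centered = base - base.mean(axis=0)
        for ax in np.eye(3):
            rigid.append(np.cross(centered, ax).ravel())
        v = rng.normal(0, 1, n_atoms * 3)
        for r in rigid:
            r = r / np.linalg.norm(r)
            v -= (v @ r) * r
        v /= np.linalg.norm(v)
        q = rng.normal(0, 1.5, n_frames)
        noise = rng.normal(0, 0.05, (n_frames, n_atoms * 3))
        coords = base.ravel()[None] + q[:, None] * v[None] + noise
        return _traj_from_coords(coords.reshape(n_frames, n_atoms, 3)), q

    def test_planted_collective_mode_recovered(self):
        traj, q = self._planted_mode_traj()
        res = trajectory_pca(traj)
        assert res.variance_fractions[0] >= 0.9
        corr = np.corrcoef(res.projections[:, 0], q)[0, 1]
        assert abs(corr) >= 0.95

    def test_eigenvalue_sum_equals_trace(self, peptide_traj):
        traj, _ = peptide_traj
        res = trajectory_pca(traj, selection="protein")
        assert res.eigenvalues.sum() == pytest.approx(res.total_variance, rel=1e-8)

    def test_static_trajectory_all_zero_eigenvalues(self, static_traj):
        traj, _ = static_traj
        res = trajectory_pca(traj)
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_projections_centered_and_components_orthonormal(self, peptide_traj):
        traj, _ = peptide_traj
        res = trajectory_pca(traj, selection="protein")
        assert np.allclose(res.projections.mean(axis=0), 0.0, atol=1e-8)
        gram = res.eigenvectors.T @ res.eigenvectors
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)


class TestFel:
    def test_single_occupied_bin(self):
        surf = free_energy_landscape(np.zeros(50), np.zeros(50), bins=4)
        assert surf.energy[~surf.empty].min() == 0.0
        assert (~surf.empty).sum() == 1

    def test_two_bin_boltzmann_gap(self):
        n1, n2 = 2_718_282, 1_000_000
        pc1 = np.concatenate([np.full(n1, -1.0), np.full(n2, 1.0)])
        pc2 = np.zeros(n1 + n2)
        surf = free_energy_landscape(pc1, pc2, bins=2, temperature=300.0)
        occupied = surf.energy[~surf.empty]
        gap = occupied.max() - occupied.min()
        kt = KB_KCAL * 300.0
        assert gap == pytest.approx(kt * np.log(n1 / n2), abs=1e-12)
        assert gap == pytest.approx(kt, abs=1e-6)

    def test_pairwise_bins_follow_boltzmann_exactly(self):
        rng = np.random.default_rng(0)
        surf = free_energy_landscape(rng.normal(0, 1, 4000), rng.normal(0, 1, 4000), bins=6)
        counts, energy = surf.counts, surf.energy
        occ = np.argwhere(counts > 0)
        kt = KB_KCAL * 300.0
        for (i1, j1), (i2, j2) in zip(occ[:-1], occ[1:]):
            lhs = energy[i1, j1] - energy[i2, j2]
            rhs = -kt * np.log(counts[i1, j1] / counts[i2, j2])
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_uniform_occupancy_flat_surface(self):
        pc = np.repeat(np.array([-0.5, 0.5]), 100)
        surf = free_energy_landscape(pc, pc, bins=2)
        assert surf.energy[~surf.empty].max() == 0.0

    def test_empty_bins_flagged_above_max(self):
        surf = free_energy_landscape(np.zeros(10), np.zeros(10), bins=3)
        assert surf.empty.sum() == 8
        assert np.all(surf.energy[surf.empty] > surf.energy[~surf.empty].max())


class TestBindingSite:
    def _complex(self, lig_offset):
        records = []
        coords = []
        for r in range(3):
            records.append((r + 1, "ALA", "CA", "C", True, 12.011))
            records.append((r + 1, "ALA", "N", "N", True, 14.007))
            coords.append([4.0 * r, 0.0, 0.0])
            coords.append([4.0 * r, 1.2, 0.0])
        records.append((9, "LIG", "C1", "C", False, 12.011))
        coords.append(lig_offset)
        traj = Trajectory(np.asarray(coords)[None], make_atom_table(records))
        return traj

    def test_far_ligand_gives_empty_selection(self):
        traj = self._complex([100.0, 0.0, 0.0])
        assert len(binding_site_selection(traj)) == 0

    def test_nearby_residue_selected_with_backbone_atoms(self):
        # CA atoms at x = 0, 4, 8; the ligand sits 4.9 A from residue 1 only
        traj = self._complex([-4.9, 0.0, 0.0])
        sel = binding_site_selection(traj, cutoff=5.0)
        residues = set(traj.atoms["residue_index"].to_numpy()[sel.indices])
        assert residues == {1}
        assert len(sel) == 2  # both backbone atoms of residue 1

    def test_three_residue_boundary_enumeration(self):
        records = [
            (1, "ALA", "CA", "C", True, 12.011),
            (2, "ALA", "CA", "C", True, 12.011),
            (3, "ALA", "CA", "C", True, 12.011),
            (9, "LIG", "C1", "C", False, 12.011),
        ]
        coords = np.array([[[4.9, 0, 0], [5.0, 0, 0], [5.1, 0, 0], [0.0, 0, 0]]])
        traj = Trajectory(coords, make_atom_table(records))
        sel = binding_site_selection(traj, cutoff=5.0, backbone_only=False)
        residues = sorted(set(traj.atoms["residue_index"].to_numpy()[sel.indices]))
        assert residues == [1, 2]
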