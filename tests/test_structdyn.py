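"""Superposition, RMSD/RMSF, PCA, SASA and anchor classification."""

import numpy as np
import pytest

from pipbind.errors import ParseError, SelectionError, SeriesValidationError
from pipbind.structdyn import (
    Trajectory,
    classify_anchor,
    delta_sasa,
    hbond_presence,
    pca_snapshots,
    read_multimodel_pdb,
    rmsd_series,
    rmsf,
    sasa,
    superpose,
    write_multimodel_pdb,
)
from pipbind.structdyn.sasa import atom_sasa, sphere_points
from pipbind.structdyn.trajectory import AtomRecord
from pipbind.synthetic import make_toy_complex, make_toy_trajectory


def rotation(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def quaternion_rmsd(A, B):
    """Independent superposition RMSD via Horn's quaternion method."""
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    Sxx = B0.T @ A0
    S = Sxx
    K = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(A0 ** 2) + np.sum(B0 ** 2) - 2 * lam) / A.shape[0]
    return np.sqrt(max(msd, 0.0))


def toy_coords(n=12, seed=0):
    return np.random.default_rng(seed).normal(0, 5, (n, 3))


class TestSuperpose:
    def test_identity(self):
        A = toy_coords()
        R, t, rmsd = superpose(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self):
        A = toy_coords()
        B = A @ rotation([0, 0, 1], np.pi / 2).T + np.array([3.0, -2.0, 7.0])
        _, _, rmsd = superpose(A, B)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            A = rng.normal(0, 5, (15, 3))
            B = A + rng.normal(0, 1, (15, 3))
            _, _, rmsd = superpose(A, B)
            assert rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-9)

    def test_applied_transform_superposes(self):
        rng = np.random.default_rng(5)
        A = rng.normal(0, 5, (10, 3))
        B = A @ rotation([1, 1, 0], 1.1).T + 4.0
        R, t, _ = superpose(A, B)
        assert np.allclose(B @ R.T + t, A, atol=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(SeriesValidationError):
            superpose(toy_coords(2), toy_coords(2))

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(SeriesValidationError):
            superpose(line, line + 1.0)


class TestRmsdRmsf:
    def test_static_trajectory_zero(self):
        coords = toy_coords()
        traj = Trajectory(np.repeat(coords[None], 4, axis=0),
                          [AtomRecord(i + 1, "GLY", "CA", "A", "C") for i in range(len(coords))])
        assert np.allclose(rmsd_series(traj), 0.0)
        assert np.allclose(rmsf(traj), 0.0)

    def test_single_displaced_atom_matches_oracle(self):
        coords = toy_coords(10)
        moved = coords.copy()
        moved[0] += np.array([1.0, 0.0, 0.0])
        traj = Trajectory(np.stack([coords, moved]),
                          [AtomRecord(i + 1, "GLY", "CA", "A", "C") for i in range(10)])
        vals = rmsd_series(traj)
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(quaternion_rmsd(coords, moved), abs=1e-9)

    def test_two_frame_oscillation_rmsf(self):
        # one residue moving +/- a along x about its mean: RMSF = a
        n = 8
        a = 0.7
        base = toy_coords(n, seed=6)
        f1, f2 = base.copy(), base.copy()
        f1[3, 0] += a
        f2[3, 0] -= a
        traj = Trajectory(np.stack([f1, f2]),
                          [AtomRecord(i + 1, "GLY", "CA", "A", "C") for i in range(n)])
        vals = rmsf(traj, align=False)
        assert vals[3] == pytest.approx(a, rel=1e-12)
        assert np.allclose(np.delete(vals, 3), 0.0, atol=1e-12)

    def test_imposed_profile_recovered(self):
        # enough residues that rigid-body alignment absorbs little of the
        # local fluctuations
        profile = np.full(40, 0.5)
        profile[[12, 25]] = 1.5
        traj = make_toy_trajectory(500, profile, seed=7)
        recovered = rmsf(traj)
        assert set(np.argsort(recovered)[-2:]) == {12, 25}
        assert np.allclose(recovered, profile, rtol=0.10)

    def test_bad_ref_frame(self):
        traj = make_toy_trajectory(5, np.full(5, 0.3), seed=0)
        with pytest.raises(SeriesValidationError):
            rmsd_series(traj, ref_frame=9)

    def test_rmsf_single_frame_rejected(self):
        traj = make_toy_trajectory(5, np.full(5, 0.3), seed=0)
        one = Trajectory(traj.frames[:1], traj.atoms)
        with pytest.raises(SeriesValidationError):
            rmsf(one)


class TestPca:
    def _traj(self, n_frames=60, seed=8):
        rng = np.random.default_rng(seed)
        base = toy_coords(9, seed=9) * 3
        frames = np.repeat(base[None], n_frames, axis=0)
        # impose dominant motion along one coordinate of one atom
        frames[:, 2, 0] += rng.normal(0, 2.0, n_frames)
        frames[:, 5, 1] += rng.normal(0, 0.2, n_frames)
        atoms = [AtomRecord(i + 1, "GLY", "CA", "A", "C") for i in range(9)]
        return Trajectory(frames, atoms)

    def test_single_mode_dominates(self):
        res = pca_snapshots(self._traj(), align=False)
        assert res.explained_variance_ratio()[0] > 0.98

    def test_trace_identity_and_orthonormality(self):
        traj = self._traj()
        res = pca_snapshots(traj, align=False)
        X = traj.frames.reshape(traj.n_frames, -1)
        total_var = ((X - X.mean(axis=0)) ** 2).mean(axis=0).sum()
        assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)
        gram = res.components @ res.components.T
        assert np.allclose(gram, np.eye(len(res.eigenvalues)), atol=1e-9)

    def test_matches_brute_force_covariance(self):
        traj = self._traj(n_frames=40)
        res = pca_snapshots(traj, align=False)
        X = traj.frames.reshape(traj.n_frames, -1)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / traj.n_frames
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        k = len(res.eigenvalues)
        assert np.allclose(res.eigenvalues, evals[:k], rtol=1e-9, atol=1e-12)
        proj = Xc @ res.components.T
        assert np.allclose(np.abs(proj), np.abs(res.projections), atol=1e-9)

    def test_projections_reconstruct_centered_coordinates(self):
        traj = self._traj(n_frames=30)
        res = pca_snapshots(traj, align=False)
        X = traj.frames.reshape(traj.n_frames, -1)
        Xc = X - X.mean(axis=0)
        recon = res.projections @ res.components
        assert np.allclose(recon, Xc, atol=1e-8)

    def test_drop_residues_excluded(self):
        traj = self._traj()
        full = pca_snapshots(traj, align=False)
        dropped = pca_snapshots(traj, drop_residues=(3, 3), align=False)
        # atom with residue_index 3 carried the dominant motion; without it
        # the leading eigenvalue collapses to the secondary mode
        assert dropped.eigenvalues[0] < 0.05 * full.eigenvalues[0]
        assert dropped.components.shape[1] == full.components.shape[1] - 3

    def test_too_few_frames(self):
        traj = self._traj()
        with pytest.raises(SeriesValidationError):
            pca_snapshots(Trajectory(traj.frames[:2], traj.atoms))

    def test_rotation_invariant_spectrum(self):
        traj = self._traj()
        R = rotation([1, 2, 3], 0.8)
        rotated = Trajectory(traj.frames @ R.T + np.array([5.0, -3.0, 2.0]),
                             traj.atoms)
        a = pca_snapshots(traj, align=True)
        b = pca_snapshots(rotated, align=True)
        assert np.allclose(a.eigenvalues, b.eigenvalues, rtol=1e-6, atol=1e-12)


class TestSasa:
    def test_single_atom_analytic(self):
        area = atom_sasa(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)[0]
        assert area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-6)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = atom_sasa(coords, np.array([1.7, 1.52]), 1.4, 960)
        singles = [
            atom_sasa(np.zeros((1, 3)), np.array([r]), 1.4, 960)[0]
            for r in (1.7, 1.52)
        ]
        assert np.allclose(areas, singles)

    def test_caged_atom_buried(self):
        comp, mask = make_toy_complex(n_peptide=3, buried=(1,))
        coords = comp.frames[0]
        areas = atom_sasa(coords, np.full(len(coords), 1.7), 1.4, 240)
        buried_idx = np.flatnonzero(mask)[1]  # chain A residue 2, inside cage
        assert areas[buried_idx] == pytest.approx(0.0, abs=1e-9)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(0, 3, (20, 3))
        radii = np.full(20, 1.7)
        a1 = atom_sasa(coords, radii, 1.4, 960)
        a2 = atom_sasa(coords, radii, 1.4, 1920)
        assert np.abs(a1.sum() - a2.sum()) / a2.sum() < 0.01

    def test_unknown_element_listed(self):
        traj = Trajectory(np.zeros((1, 1, 3)),
                          [AtomRecord(1, "UNK", "XX", "A", "Xx")])
        with pytest.raises(SeriesValidationError, match="XX"):
            sasa(traj)

    def test_sphere_points_on_unit_sphere(self):
        pts = sphere_points(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestDeltaSasa:
    def test_toy_complex_burial_pattern(self):
        comp, mask = make_toy_complex(n_peptide=5, buried=(1, 3), seed=2)
        table = delta_sasa(comp, mask, n_points=480)
        buried = table.loc[[2, 4], "delta_sasa"]
        exposed = table.loc[[1, 3, 5], "delta_sasa"]
        # buried residues lose their whole isolated surface
        assert np.allclose(buried, table.loc[[2, 4], "sasa_free"], atol=0.5)
        assert np.all(np.abs(exposed) < 0.5)

    def test_far_ligand_all_zero(self):
        comp, mask = make_toy_complex(n_peptide=4, buried=(1,))
        shifted = comp.frames.copy()
        shifted[0, mask] += np.array([0.0, 0.0, 500.0])
        far = Trajectory(shifted, comp.atoms)
        table = delta_sasa(far, mask, n_points=240)
        assert np.all(np.abs(table["delta_sasa"]) < 1e-9)

    def test_non_negative_up_to_sampling(self):
        comp, mask = make_toy_complex(seed=5)
        table = delta_sasa(comp, mask, n_points=240)
        assert np.all(table["delta_sasa"] > -0.5)

    def test_empty_selection_rejected(self):
        comp, mask = make_toy_complex()
        with pytest.raises(SelectionError):
            delta_sasa(comp, np.zeros_like(mask))

    def test_against_independent_engine(self):
        """Cross-check against biotite's Shrake–Rupley implementation."""
        biotite_struc = pytest.importorskip("biotite.structure")
        comp, mask = make_toy_complex(n_peptide=4, buried=(2,), seed=3)
        coords = comp.frames[0]
        arr = biotite_struc.AtomArray(len(coords))
        arr.coord = coords
        arr.element = np.array(["C"] * len(coords))
        arr.atom_name = np.array(["CA"] * len(coords))
        arr.res_id = np.arange(1, len(coords) + 1)
        arr.res_name = np.array(["GLY"] * len(coords))
        arr.chain_id = np.array(["A"] * len(coords))
        ours = atom_sasa(coords, np.full(len(coords), 1.7), 1.4, 960)
        theirs = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=960,
            vdw_radii="Single", ignore_ions=False,
        )
        # replace biotite's per-element radii effects: compare only C atoms
        assert np.allclose(ours, theirs, rtol=0.02, atol=0.5)


class TestClassifyAnchor:
    def test_threshold_and_evidence_rules(self):
        delta = {1: 130.0, 2: 32.7, 3: 70.0, 4: 5.0}
        evidence = {2: ["backbone O of receptor residue 232"]}
        table = classify_anchor(delta, evidence).table
        assert table.loc[1, "class"] == "anchor"
        assert table.loc[2, "class"] == "tether"
        assert table.loc[3, "class"] == "other"  # strict inequality at 70
        assert table.loc[4, "class"] == "other"

    def test_toy_complex_anchors(self):
        comp, mask = make_toy_complex(n_peptide=5, buried=(0, 4), seed=8)
        table = delta_sasa(comp, mask, n_points=480)
        anchors = classify_anchor(table).anchors()
        assert anchors == [1, 5]


class TestHbonds:
    def _traj(self, d_pos, a_pos, h_pos=None):
        atoms = [AtomRecord(1, "ASN", "ND2", "A", "N"),
                 AtomRecord(2, "ASP", "OD1", "B", "O")]
        coords = [d_pos, a_pos]
        if h_pos is not None:
            atoms.append(AtomRecord(1, "ASN", "HD2", "A", "H"))
            coords.append(h_pos)
        return Trajectory(np.array(coords)[None], atoms)

    def test_close_pair_present(self):
        traj = self._traj([0, 0, 0], [2.8, 0, 0], [1.0, 0, 0])
        table = hbond_presence(traj, [(0, 2, 1)])
        assert bool(table.iloc[0, 0])

    def test_far_pair_absent(self):
        traj = self._traj([0, 0, 0], [5.0, 0, 0])
        table = hbond_presence(traj, [(0, 1)])
        assert not bool(table.iloc[0, 0])

    def test_boundary_conventions(self):
        # distance exactly 3.5 A (exactly representable) is inclusive
        traj = self._traj([0.0, 0, 0], [3.5, 0, 0], [1.0, 0, 0])
        assert bool(hbond_presence(traj, [(0, 2, 1)]).iloc[0, 0])
        # angle threshold is inclusive: just above 120 deg present, just
        # below absent, at the same 2.8 A donor-acceptor distance
        for eps, expect in ((+1e-4, True), (-1e-4, False)):
            ang = np.radians(120.0 + eps)
            h = np.array([1.0, 0.0, 0.0])
            direction = np.array([-np.cos(ang), np.sin(ang), 0.0])
            from scipy.optimize import brentq

            L = brentq(
                lambda l: np.linalg.norm(h + l * direction) - 2.8, 0.1, 10.0
            )
            a = h + L * direction
            traj = self._traj([0.0, 0, 0], a, h)
            assert bool(hbond_presence(traj, [(0, 2, 1)]).iloc[0, 0]) is expect

    def test_unresolvable_atom(self):
        traj = self._traj([0, 0, 0], [3.0, 0, 0])
        with pytest.raises(SelectionError):
            hbond_presence(traj, [(("A", 1, "NE2"), ("B", 2, "OD1"))])


class TestPdbRoundTrip:
    def test_round_trip(self, tmp_path):
        traj = make_toy_trajectory(4, np.full(6, 0.5), seed=12)
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 4
        assert back.n_atoms == 6
        assert np.allclose(back.frames, traj.frames, atol=1.5e-3)
        assert [a.key() for a in back.atoms] == [a.key() for a in traj.atoms]

    def test_mismatched_models_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  GLY A   2       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        with pytest.raises(ParseError, match="model 2"):
            read_multimodel_pdb(path)

    def test_geometric_invariance_of_analytics(self):
        traj = make_toy_trajectory(50, np.array([0.3, 0.3, 1.0, 0.3, 0.3, 0.3]), seed=13)
        R = rotation([0, 1, 1], 0.9)
        moved = Trajectory(traj.frames @ R.T + 7.0, traj.atoms)
        assert np.allclose(rmsd_series(traj), rmsd_series(moved), atol=1e-9)
        assert np.allclose(rmsf(traj), rmsf(moved), atol=1e-9)
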