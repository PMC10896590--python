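"""Superposition, RMSD/RMSF, DCCM, communication networks, monitors."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from bindkin.structure import (
    CALPHA,
    SelectionSpec,
    StructureFrame,
    Trajectory,
    communication_network,
    contact_map,
    dccm,
    dihedral,
    dihedral_series,
    distance_series,
    kabsch_superpose,
    parse_selection,
    rmsd_series,
    rmsf,
    shortest_path,
    superpose_coords,
)
from bindkin.synthdata import frames_to_trajectory, make_correlated_frames


def ca_frame(coords, resids=None):
    n = len(coords)
    return StructureFrame(
        names=np.array(["CA"] * n),
        resnames=np.array(["GLY"] * n),
        resids=np.arange(1, n + 1) if resids is None else np.asarray(resids),
        chains=np.array(["A"] * n),
        elements=np.array(["C"] * n),
        coords=np.asarray(coords, dtype=float),
    )


class TestSuperposition:
    def test_identity_on_self(self):
        f = ca_frame(np.random.default_rng(0).normal(size=(6, 3)) * 4)
        moved, rmsd = kabsch_superpose(f, f, CALPHA)
        assert rmsd < 1e-12
        assert np.allclose(moved.coords, f.coords, atol=1e-12)

    def test_rigid_transform_removed(self):
        rng = np.random.default_rng(1)
        xyz = rng.normal(size=(8, 3)) * 5
        R = Rotation.random(rng=np.random.default_rng(2)).as_matrix()
        f_ref = ca_frame(xyz)
        f_mov = ca_frame(xyz @ R.T + [4.0, -1.0, 2.0])
        _, rmsd = kabsch_superpose(f_mov, f_ref, CALPHA)
        assert rmsd < 1e-10

    def test_matches_brute_force_rotation_search(self):
        """Kabsch RMSD equals a rotation-space search minimum within 1e-6
        on a random 5-atom pair (independent of the SVD route)."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 3)) * 3
        b = rng.normal(size=(5, 3)) * 3
        _, _, kabsch = superpose_coords(a, b)
        ac, bc = a - a.mean(0), b - b.mean(0)

        def cost(rotvec):
            Rm = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((ac @ Rm.T - bc) ** 2, axis=1)))

        best = np.inf
        for quat in Rotation.random(150, rng=np.random.default_rng(4)):
            start = quat.as_rotvec()
            res = minimize(cost, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        assert abs(best - kabsch) < 1e-6

    def test_mismatched_selection_rejected(self):
        f1 = ca_frame(np.zeros((3, 3)) + np.arange(3)[:, None])
        f2 = ca_frame(np.zeros((3, 3)) + np.arange(3)[:, None], resids=[1, 2, 9])
        with pytest.raises(ValueError, match="unpaired"):
            kabsch_superpose(f1, f2, CALPHA)


class TestRmsdRmsf:
    def test_static_trajectory_zero_rmsf(self):
        base = np.random.default_rng(5).normal(size=(7, 3)) * 3
        traj = Trajectory(ca_frame(base), np.repeat(base[None], 5, axis=0))
        assert np.allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_two_frame_oscillation_closed_form(self):
        """One atom moving ±d along x (others pinned, no superposition):
        its RMSF equals d."""
        base = np.zeros((4, 3))
        base[:, 0] = [0.0, 10.0, 20.0, 30.0]
        d = 0.7
        c1, c2 = base.copy(), base.copy()
        c1[2, 0] += d
        c2[2, 0] -= d
        traj = Trajectory(ca_frame(base), np.stack([c1, c2]))
        out = rmsf(traj, superpose=False)
        assert out[2] == pytest.approx(d, abs=1e-12)
        assert np.allclose(np.delete(out, 2), 0.0, atol=1e-12)

    def test_gaussian_frames_rmsf_sigma_sqrt3(self):
        sigma = 0.4
        coords = make_correlated_frames(np.eye(12) * sigma**2, 6000, seed=8)
        traj = frames_to_trajectory(coords)
        out = rmsf(traj, superpose=False)
        assert np.allclose(out, sigma * np.sqrt(3), rtol=0.05)

    def test_rmsd_series_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(6, 3)) * 4
        frames = base[None] + rng.normal(scale=0.1, size=(4, 6, 3))
        traj = Trajectory(ca_frame(base), frames)
        ref = ca_frame(base)
        s1 = rmsd_series(traj, ref, CALPHA)
        R = Rotation.random(rng=np.random.default_rng(10)).as_matrix()
        traj2 = Trajectory(ca_frame(base), frames @ R.T + [1.0, 2.0, 3.0])
        s2 = rmsd_series(traj2, ref, CALPHA)
        assert np.allclose(s1, s2, atol=1e-9)

    def test_single_frame_rmsf_rejected(self):
        base = np.random.default_rng(5).normal(size=(4, 3))
        traj = Trajectory(ca_frame(base), base[None])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(traj)


class TestDccm:
    def test_diagonal_is_one_and_symmetric(self):
        coords = make_correlated_frames(np.eye(5), 300, seed=1)
        c = dccm(coords)
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c, c.T)

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 1))
        disp = np.concatenate([x, -x], axis=1)[:, :, None] * np.array([1.0, 0, 0])
        c = dccm(disp + np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        assert c[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_recovers_generating_covariance(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(6, 6))
        cov = A @ A.T + 0.3 * np.eye(6)
        n_frames = 4000
        c = dccm(make_correlated_frames(cov, n_frames, seed=13))
        truth = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert np.max(np.abs(c - truth)) < 4 / np.sqrt(n_frames)

    def test_zero_variance_atom_flagged(self):
        coords = make_correlated_frames(np.diag([1.0, 0.0, 1.0]), 100, seed=3)
        with pytest.warns(UserWarning, match="zero-variance"):
            c = dccm(coords)
        assert np.isnan(c[1, 0]) and np.isnan(c[0, 1])

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            make_correlated_frames(bad, 10, seed=0)


class TestNetwork:
    def test_three_node_chain_path(self):
        corr = np.array([[1.0, 0.999, 0.999],
                         [0.999, 1.0, 0.999],
                         [0.999, 0.999, 1.0]])
        g = communication_network(corr, [(0, 1), (1, 2)])  # no 0-2 contact
        path, _ = shortest_path(g, 0, 2)
        assert path == [0, 1, 2]

    def test_no_path_signalled(self):
        g = communication_network(np.eye(3), [(0, 1)])
        with pytest.raises(ValueError, match="no communication path"):
            shortest_path(g, 0, 2)

    def test_nan_rows_excluded(self):
        corr = np.array([[1.0, np.nan], [np.nan, 1.0]])
        g = communication_network(corr, [(0, 1)])
        assert g.number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """Dijkstra shortest paths equal brute-force enumeration over all
        simple paths on random graphs with <= 7 nodes."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 8)
        corr = rng.uniform(-0.99, 0.99, size=(n, n))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        contacts = [(i, j) for i in range(n) for j in range(i + 1, n)
                    if rng.random() < 0.6]
        g = communication_network(corr, contacts)
        w = {frozenset(e): -np.log(np.clip(abs(corr[e[0], e[1]]), 1e-12, 1 - 1e-12))
             for e in contacts}

        def brute(source, target):
            best = np.inf
            nodes = set(range(n)) - {source, target}
            for r in range(len(nodes) + 1):
                for mid in itertools.permutations(nodes, r):
                    path = (source, *mid, target)
                    try:
                        cost = sum(w[frozenset((path[k], path[k + 1]))]
                                   for k in range(len(path) - 1))
                    except KeyError:
                        continue
                    best = min(best, cost)
            return best

        for s in range(n):
            for t in range(s + 1, n):
                expected = brute(s, t)
                try:
                    _, got = shortest_path(g, s, t)
                except ValueError:
                    assert expected == np.inf
                    continue
                assert got == pytest.approx(expected, abs=1e-12)

    def test_strengthening_correlation_never_lengthens_path(self):
        corr = np.array([[1.0, 0.5, 0.1],
                         [0.5, 1.0, 0.5],
                         [0.1, 0.5, 1.0]])
        contacts = [(0, 1), (1, 2), (0, 2)]
        _, before = shortest_path(communication_network(corr, contacts), 0, 2)
        corr2 = corr.copy()
        corr2[0, 1] = corr2[1, 0] = 0.9
        _, after = shortest_path(communication_network(corr2, contacts), 0, 2)
        assert after <= before

    def test_contact_map_cutoff(self):
        base = np.zeros((3, 3))
        base[1, 0] = 5.0
        base[2, 0] = 30.0
        traj = Trajectory(ca_frame(base), np.repeat(base[None], 4, axis=0))
        contacts = contact_map(traj, CALPHA, cutoff=8.0, min_fraction=0.75)
        assert contacts == [(0, 1)]


class TestMonitors:
    def test_dihedral_cis_trans(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_collinear_flagged_nan(self):
        assert np.isnan(dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0]))

    def test_distance_345(self):
        base = np.array([[0.0, 0, 0], [3.0, 4.0, 0.0]])
        traj = Trajectory(ca_frame(base), base[None])
        d = distance_series(traj, ("A", 1, "CA"), ("A", 2, "CA"))
        assert d[0] == pytest.approx(5.0)

    def test_dihedral_series_over_frames(self):
        base = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        flipped = base.copy()
        flipped[3] = [1, -1, 0]
        traj = Trajectory(ca_frame(base), np.stack([base, flipped]))
        series = dihedral_series(traj, [("A", i, "CA") for i in (1, 2, 3, 4)])
        assert series == pytest.approx([0.0, 180.0])

    def test_missing_atom_keyerror(self):
        base = np.zeros((2, 3))
        base[1, 0] = 3.0
        traj = Trajectory(ca_frame(base), base[None])
        with pytest.raises(KeyError):
            distance_series(traj, ("A", 1, "CA"), ("B", 9, "CB"))


class TestSelections:
    def test_parse_grammar(self):
        sel = parse_selection("name CA,CB and resid 5:20 and chain A")
        assert sel.names == ("CA", "CB")
        assert sel.resid_range == (5, 20)
        assert sel.chain == "A"
        assert parse_selection("backbone").names == ("N", "CA", "C", "O")
        assert parse_selection("calpha").names == ("CA",)

    def test_bad_clause_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_selection("within 5 of ligand")

    def test_empty_selection_rejected(self):
        f = ca_frame(np.zeros((2, 3)) + np.arange(2)[:, None])
        with pytest.raises(ValueError, match="matches no atoms"):
            SelectionSpec(names=("CB",)).mask(f)
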