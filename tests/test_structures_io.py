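"""Structure/trajectory I/O, atom selection, and Kabsch RMSD."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cesakit import structures_io as sio
from cesakit import synthetic_data as sd

TOY_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  HG  SER A   1       0.500   0.800   0.000  1.00  0.00           H
END
"""

MULTI_MODEL_PDB = """\
MODEL        1
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  HG  SER A   1       0.500   0.800   0.000  1.00  0.00           H
ENDMDL
MODEL        2
ATOM      1  N   SER A   1       1.000   0.000   0.000  1.00  0.00           N
ATOM      2  HG  SER A   1       1.500   0.800   0.000  1.00  0.00           H
ENDMDL
MODEL        3
ATOM      1  N   SER A   1       2.000   0.000   0.000  1.00  0.00           N
ATOM      2  HG  SER A   1       2.500   0.800   0.000  1.00  0.00           H
ENDMDL
"""


@pytest.fixture()
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


class TestReadStructure:
    def test_identity_parse(self, toy_pdb):
        topo, frame = sio.read_structure(toy_pdb)
        assert topo.n_atoms == 2
        assert topo.atoms[0].name == "N"
        assert topo.atoms[1].is_hydrogen
        np.testing.assert_allclose(frame.coordinates[1], [0.5, 0.8, 0.0])

    def test_multi_model_returns_first_with_warning(self, tmp_path):
        p = tmp_path / "multi.pdb"
        p.write_text(MULTI_MODEL_PDB)
        with pytest.warns(UserWarning, match="3 models"):
            topo, frame = sio.read_structure(p)
        assert frame.coordinates[0, 0] == 0.0

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  N   SER A   1       junk\n")
        with pytest.raises(sio.PDBParseError, match="line 1"):
            sio.read_structure(p)

    def test_element_inferred_when_column_missing(self, tmp_path):
        line = "ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
        p = tmp_path / "noelem.pdb"
        p.write_text(line + "\n")
        topo, _ = sio.read_structure(p)
        assert topo.atoms[0].element == "C"


class TestTrajectoryIO:
    def test_three_model_file_gives_three_frames(self, tmp_path):
        p = tmp_path / "multi.pdb"
        p.write_text(MULTI_MODEL_PDB)
        traj = sio.read_trajectory(p)
        assert traj.n_frames == 3
        assert [f.coordinates[0, 0] for f in traj.frames] == [0.0, 1.0, 2.0]

    def test_read_is_deterministic(self, tmp_path):
        p = tmp_path / "multi.pdb"
        p.write_text(MULTI_MODEL_PDB)
        a = sio.read_trajectory(p)
        b = sio.read_trajectory(p)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.coordinates, fb.coordinates)

    def test_atom_count_mismatch_names_frame(self, tmp_path, toy_pdb):
        topo, _ = sio.read_structure(toy_pdb)
        bad = tmp_path / "bad.pdb"
        bad.write_text(
            "MODEL        1\n"
            "ATOM      1  N   SER A   1       0.000   0.000   0.000\n"
            "ENDMDL\n"
        )
        with pytest.raises(ValueError, match="frame 0"):
            sio.read_trajectory(bad, topology=topo)

    def test_generator_roundtrip_at_write_precision(self, tmp_path):
        res = sd.synth_trajectory(sd.TrajectorySpec(
            pairs=(sd.PairSpec("SER", 80, 40, 0),), n_frames=5, seed=0))
        out = tmp_path / "t.pdb"
        sio.write_trajectory(out, res.trajectory)
        back = sio.read_trajectory(out)
        assert back.n_frames == res.trajectory.n_frames
        for fa, fb in zip(res.trajectory.frames, back.frames):
            # PDB prints 3 decimals; the round-trip is exact at that grid
            np.testing.assert_allclose(fa.coordinates, fb.coordinates,
                                       atol=5.0e-4)
        again = tmp_path / "t2.pdb"
        sio.write_trajectory(again, back)
        assert out.read_text() == again.read_text()

    def test_mdanalysis_reads_the_same_coordinates(self, tmp_path):
        mda = pytest.importorskip("MDAnalysis")
        res = sd.synth_trajectory(sd.TrajectorySpec(
            pairs=(sd.PairSpec("PHE", 50, 0, 25),), n_frames=4, seed=0))
        out = tmp_path / "t.pdb"
        sio.write_trajectory(out, res.trajectory)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(out))
        assert len(u.atoms) == res.trajectory.topology.n_atoms
        ours = sio.read_trajectory(out)
        for k, _ in enumerate(u.trajectory):
            np.testing.assert_allclose(u.atoms.positions,
                                       ours.frames[k].coordinates, atol=1e-3)


class TestNonbondedParams:
    def test_table_attaches_and_net_charge(self, tmp_path):
        res = sd.synth_trajectory(sd.TrajectorySpec(
            pairs=(sd.PairSpec("SER", 40, 20, 0),), n_frames=5, seed=0))
        topo = res.trajectory.topology
        path = tmp_path / "nb.tsv"
        sio.write_nonbonded_params(path, topo, res.params)
        params = sio.read_nonbonded_params(path, topo)
        np.testing.assert_allclose(params.charge, res.params.charge, atol=1e-12)
        glucan = [i for i, c in enumerate(topo.molecule_class) if c == "glucan"]
        assert abs(params.charge[glucan].sum()) < 1e-9  # designed net charge 0

    def test_duplicate_key_row_rejected(self, tmp_path, rng):
        res = sd.synth_trajectory(sd.TrajectorySpec(
            pairs=(sd.PairSpec("LEU", 20, 0, 0),), n_frames=5, seed=0))
        path = tmp_path / "nb.tsv"
        sio.write_nonbonded_params(path, res.trajectory.topology, res.params)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            sio.read_nonbonded_params(path, res.trajectory.topology)

    def test_unmatched_atom_lists_missing_keys(self, tmp_path):
        res = sd.synth_trajectory(sd.TrajectorySpec(
            pairs=(sd.PairSpec("LEU", 20, 0, 0),), n_frames=5, seed=0))
        path = tmp_path / "nb.tsv"
        sio.write_nonbonded_params(path, res.trajectory.topology, res.params)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError, match="does not cover"):
            sio.read_nonbonded_params(path, res.trajectory.topology)


@pytest.fixture(scope="module")
def topo():
    res = sd.synth_trajectory(sd.TrajectorySpec(
        pairs=(sd.PairSpec("SER", 40, 20, 0), sd.PairSpec("PHE", 40, 0, 20)),
        n_frames=5, seed=0))
    return res.trajectory.topology


class TestSelectAtoms:

    def test_heavy_excludes_hydrogens(self, topo):
        idx = sio.select_atoms(topo, "chain A and heavy")
        assert all(not topo.atoms[i].is_hydrogen for i in idx)
        assert idx  # non-empty

    def test_sidechain_excludes_backbone(self, topo):
        idx = sio.select_atoms(topo, "chain A and sidechain")
        assert all(topo.atoms[i].name not in {"N", "CA", "C", "O"} for i in idx)

    def test_complement_property(self, topo):
        for expr in ("heavy", "chain A", "resname PHE", "sidechain",
                     "glucan and heavy"):
            sel = set(sio.select_atoms(topo, expr))
            neg = set(sio.select_atoms(topo, f"not ( {expr} )"))
            assert sel | neg == set(range(topo.n_atoms))
            assert not sel & neg

    def test_idempotent_and_set_algebra(self, topo):
        a = sio.select_atoms(topo, "chain A and heavy")
        assert sio.select_atoms(topo, "chain A and heavy") == a
        union = sio.select_atoms(topo, "chain A or chain G")
        assert set(union) == set(sio.select_atoms(topo, "chain A")) | \
            set(sio.select_atoms(topo, "chain G"))

    def test_unknown_token_errors(self, topo):
        with pytest.raises(ValueError, match="unknown selector"):
            sio.select_atoms(topo, "bogus")

    def test_resid_range(self, topo):
        idx = sio.select_atoms(topo, "chain G and resid 1-1")
        assert {topo.atoms[i].residue_index for i in idx} == {1}


def _brute_force_rmsd(A, B):
    """Numeric minimization over rotation vectors (multi-start)."""
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)

    def cost(v):
        R = Rotation.from_rotvec(v).as_matrix()
        return np.sqrt((((R @ A0.T).T - B0) ** 2).sum() / len(A0))

    best = np.inf
    for seed_vec in ([0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3], [2, 2, 2],
                     [-1, 2, -2], [3, -1, 1]):
        r = minimize(cost, np.asarray(seed_vec, float), method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 6000})
        best = min(best, r.fun)
    return best


class TestKabschRMSD:
    def test_identical_sets_are_zero(self, rng):
        A = rng.standard_normal((12, 3))
        assert sio.kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        A = rng.standard_normal((10, 3)) * 5
        R = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        B = (R @ A.T).T + np.array([10.0, -3.0, 2.5])
        assert sio.kabsch_rmsd(A, B) < 1e-8
        # symmetry and pre-rotation invariance
        assert sio.kabsch_rmsd(B, A) < 1e-8

    def test_symmetry_on_distorted_pair(self, rng):
        A = rng.standard_normal((10, 3)) * 4
        B = A + 0.3 * rng.standard_normal((10, 3))
        assert sio.kabsch_rmsd(A, B) == pytest.approx(sio.kabsch_rmsd(B, A),
                                                      abs=1e-12)

    def test_matches_numeric_minimization_oracle(self, rng):
        for _ in range(5):
            A = rng.standard_normal((10, 3)) * 3
            B = A + 0.5 * rng.standard_normal((10, 3))
            assert sio.kabsch_rmsd(A, B) == pytest.approx(
                _brute_force_rmsd(A, B), abs=1e-6)

    def test_degenerate_inputs_error(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            sio.kabsch_rmsd(line, line)
        with pytest.raises(ValueError, match="3 points"):
            sio.kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
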