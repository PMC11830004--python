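import numpy as np
import pytest

from shellkit import icosa_lattice as il
from shellkit import mrc
from shellkit import structure_io as sio
from shellkit import synthetic_shells as ss

from conftest import random_rotation


def _toy_chain(cid, coords):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return sio.Chain(
        cid,
        coords,
        np.array(["C"] * n, dtype=object),
        np.full(n, 1.7),
        res_ids=np.arange(1, n + 1),
        atom_names=np.array(["CA"] * n, dtype=object),
    )


class TestModelIO:
    @pytest.mark.parametrize("ext,tol", [("pdb", 1e-3), ("cif", 1e-4)])
    def test_round_trip_preserves_coordinates(self, tmp_path, reference_shell, ext, tol):
        path = tmp_path / f"shell.{ext}"
        sio.save_shell_model(reference_shell, path)
        back = sio.load_shell_model(path)
        assert back.n_chains == 60
        assert np.abs(back.all_coords() - reference_shell.all_coords()).max() <= tol

    def test_partial_model_round_trip_chain_count(self, tmp_path, lattice, reference_shell):
        part = ss.make_partial_model(reference_shell, set(range(12)))
        path = tmp_path / "part.pdb"
        sio.save_shell_model(part, path)
        assert sio.load_shell_model(path).n_chains == 48

    def test_duplicate_chain_ids_rejected(self, tmp_path):
        pdb = tmp_path / "dup.pdb"
        lines = []
        serial = 1
        for cid, x in (("A", 0.0), ("B", 8.0), ("A", 16.0)):
            for k in range(2):
                lines.append(
                    f"ATOM  {serial:>5} CA   ALA {cid}{k + 1:>4}    "
                    f"{x + k:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
                )
                serial += 1
            lines.append("TER")
        pdb.write_text("\n".join(lines) + "\nEND\n")
        with pytest.raises(sio.ModelParseError, match="duplicate chain ids"):
            sio.load_shell_model(pdb)

    def test_malformed_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a cif file\n")
        with pytest.raises((sio.ModelParseError, sio.EmptyModelError)):
            sio.load_shell_model(bad)

    def test_hydrogens_dropped_by_default(self, tmp_path):
        pdb = tmp_path / "h.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
            "END\n"
        )
        model = sio.load_shell_model(pdb)
        assert model.chain("A").n_atoms == 1
        model_h = sio.load_shell_model(pdb, drop_hydrogens=False)
        assert model_h.chain("A").n_atoms == 2

    def test_element_radii_attached(self, tmp_path):
        pdb = tmp_path / "el.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  N   ALA A   1       2.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      3  SG  CYS A   2       4.000   0.000   0.000  1.00  0.00           S\n"
            "END\n"
        )
        radii = sio.load_shell_model(pdb).chain("A").radii
        assert radii.tolist() == [1.70, 1.55, 1.80]

    def test_empty_model_rejected(self):
        with pytest.raises(sio.EmptyModelError):
            sio.ShellModel({})


class TestMrcIO:
    def test_round_trip_bit_exact(self, tmp_path):
        grid = np.random.default_rng(3).normal(size=(6, 7, 8)).astype(np.float32)
        path = tmp_path / "m.mrc"
        mrc.write_mrc(path, grid, 1.25, origin=(-3.0, 4.0, 0.5))
        back, voxel, origin = mrc.read_mrc(path)
        assert np.array_equal(back, grid)
        assert voxel == pytest.approx(1.25, rel=1e-6)
        assert np.allclose(origin, (-3.0, 4.0, 0.5))

    def test_header_voxel_0834(self, tmp_path):
        path = tmp_path / "m.mrc"
        mrc.write_mrc(path, np.zeros((4, 4, 4), np.float32), 0.834)
        dmap = sio.load_density_map(path)
        assert dmap.voxel_size == pytest.approx(0.834, abs=1e-6)

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "m.mrc"
        mrc.write_mrc(path, np.zeros((8, 8, 8), np.float32), 1.0)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(mrc.MrcParseError):
            mrc.read_mrc(path)

    def test_unknown_mode_rejected(self, tmp_path):
        path = tmp_path / "m.mrc"
        mrc.write_mrc(path, np.zeros((4, 4, 4), np.float32), 1.0)
        raw = bytearray(path.read_bytes())
        raw[12:16] = (99).to_bytes(4, "little")
        path.write_bytes(bytes(raw))
        with pytest.raises(mrc.UnsupportedGridError):
            mrc.read_mrc(path)

    def test_anisotropic_voxels_rejected(self, tmp_path):
        path = tmp_path / "m.mrc"
        mrc.write_mrc(path, np.zeros((4, 4, 4), np.float32), 1.0)
        raw = bytearray(path.read_bytes())
        cella = np.frombuffer(raw[40:52], "<f4").copy()
        cella[0] *= 1.3
        raw[40:52] = cella.tobytes()
        path.write_bytes(bytes(raw))
        with pytest.raises(mrc.UnsupportedGridError):
            mrc.read_mrc(path)

    def test_axis_order_normalised(self, tmp_path):
        grid = np.arange(2 * 3 * 4, dtype=np.float32).reshape(2, 3, 4)
        path = tmp_path / "m.mrc"
        mrc.write_mrc(path, grid, 1.0)
        # rewrite as a YXZ-ordered dialect
        raw = bytearray(path.read_bytes())
        hi = np.frombuffer(raw[:224], "<i4").copy()
        hf = hi.view("<f4")
        hi[0:3] = (3, 2, 4)
        hi[7:10] = (3, 2, 4)
        hf[10:13] = (3.0, 2.0, 4.0)
        hi[16:19] = (2, 1, 3)
        raw[:224] = hi.tobytes()
        permuted = np.ascontiguousarray(grid.transpose(2, 0, 1))  # sections=z, rows=x, cols=y
        path.write_bytes(bytes(raw[:1024]) + permuted.tobytes())
        back, _, _ = mrc.read_mrc(path)
        assert np.array_equal(back, grid)

    def test_mode0_int8_supported(self, tmp_path):
        path = tmp_path / "m.mrc"
        mrc.write_mrc(path, np.zeros((2, 2, 2), np.float32), 1.0)
        raw = bytearray(path.read_bytes())[:1024]
        raw[12:16] = (0).to_bytes(4, "little")
        data = np.arange(8, dtype=np.int8)
        path.write_bytes(bytes(raw) + data.tobytes())
        back, _, _ = mrc.read_mrc(path)
        assert back.ravel(order="F").tolist() == list(range(8))


class TestAssignment:
    def test_full_shell_bijection_zero_residual(self, lattice, reference_shell):
        a = sio.assign_chains_to_sites(reference_shell, lattice)
        assert sorted(a.pairs.values()) == list(range(60))
        assert a.residual < 1e-6

    def test_partial_shell_recovers_generating_sites(self, lattice, reference_shell):
        plan = set(lattice.group_members("pentamer", 3)) | set(
            lattice.group_members("dimer", 11)
        )
        part = ss.make_partial_model(reference_shell, plan)
        truth = set(reference_shell.assignment.values()) - plan
        a = sio.assign_chains_to_sites(part.subset(part.chain_ids), lattice)
        assert set(a.pairs.values()) == truth

    def test_invariant_under_chain_relabelling(self, lattice, reference_shell):
        plan = set(range(0, 12))
        part = ss.make_partial_model(reference_shell, plan)
        a1 = sio.assign_chains_to_sites(part.subset(part.chain_ids), lattice)
        shuffled = list(reversed(part.chain_ids))
        a2 = sio.assign_chains_to_sites(part.subset(shuffled), lattice)
        assert a1.pairs == a2.pairs

    def test_equivariant_under_group_rotation(self, lattice, reference_shell, oracle):
        plan = set(lattice.group_members("pentamer", 0))
        part = ss.make_partial_model(reference_shell, plan)
        a1 = sio.assign_chains_to_sites(part.subset(part.chain_ids), lattice)
        g = lattice.operators.rotations[23]
        a2 = sio.assign_chains_to_sites(part.transformed(g), lattice)
        # the derived occupancy pattern is invariant even though site labels
        # may be permuted by a group element
        assert oracle(lattice, a1.pairs.values()) == oracle(lattice, a2.pairs.values())

    def test_invariant_table_under_arbitrary_rigid_motion(
        self, lattice, reference_shell, oracle
    ):
        rng = np.random.default_rng(7)
        plan = {0, 1, 2, 13, 29, 44}
        part = ss.make_partial_model(reference_shell, plan)
        a1 = sio.assign_chains_to_sites(part.subset(part.chain_ids), lattice)
        moved = part.transformed(random_rotation(rng), rng.normal(size=3) * 20)
        a2 = sio.assign_chains_to_sites(moved, lattice)
        assert oracle(lattice, a1.pairs.values()) == oracle(lattice, a2.pairs.values())
        assert a2.residual < 1e-6

    def test_too_many_chains_rejected(self, lattice, reference_shell):
        extra = dict(reference_shell.chains)
        extra["zz"] = _toy_chain("zz", [[200.0, 0, 0], [201.0, 0, 0]])
        with pytest.raises(ValueError, match="60 sites"):
            sio.assign_chains_to_sites(sio.ShellModel(extra), lattice)

    def test_residual_cutoff_enforced(self, lattice):
        rng = np.random.default_rng(0)
        chains = {}
        for k in range(8):
            c = rng.normal(size=3)
            c = 100 * c / np.linalg.norm(c)
            chains[f"c{k}"] = _toy_chain(f"c{k}", c[None, :] + rng.normal(size=(4, 3)))
        with pytest.raises(sio.NoAssignmentError):
            sio.assign_chains_to_sites(sio.ShellModel(chains), lattice, cutoff=0.05)

    def test_single_chain_assigned(self, lattice, reference_shell):
        one = reference_shell.subset([reference_shell.chain_ids[5]])
        a = sio.assign_chains_to_sites(one, lattice)
        assert len(a.pairs) == 1

    def test_sphere_fit_recovers_center(self):
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = np.array([5.0, -2.0, 9.0]) + 57.0 * dirs
        assert np.allclose(sio.fit_sphere_center(pts), [5.0, -2.0, 9.0], atol=1e-8)

    def test_assignment_json_round_trip(self, tmp_path, lattice, reference_shell):
        import json

        a = sio.assign_chains_to_sites(reference_shell, lattice)
        path = tmp_path / "a.json"
        a.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["pairs"] == {c: s for c, s in a.pairs.items()}
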