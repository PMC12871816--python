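"""PDB and trajectory container round trips, unit conversion, errors."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tailgate as tg
from tailgate.trajio import MAGIC

from conftest import random_structure


def make_structure(coords, chains=None, mobile=None):
    n = len(coords)
    return tg.Structure(
        atom_id=np.arange(1, n + 1), atom_name=np.array(["CA"] * n),
        residue_index=np.arange(1, n + 1),
        residue_name=np.array(["GLY"] * n),
        chain_id=np.array(chains or ["A"] * n),
        coords=np.asarray(coords, dtype=float),
        mobile=np.ones(n, bool) if mobile is None else np.asarray(mobile),
    ).validate()


class TestReadStructure:
    def test_angstrom_to_nm_conversion(self):
        line = ("ATOM      1  CA  GLY A   1      10.000   0.000   0.000"
                "  1.00  0.00")
        s = tg.read_structure(line + "\n")
        assert s.n_atoms == 1
        assert s.coords[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(tg.ValidationError, match="no atoms"):
            tg.read_structure("")

    def test_three_atom_roundtrip_identity(self):
        s = make_structure([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]],
                           chains=["A", "A", "B"], mobile=[True, False, True])
        s2 = tg.read_structure(tg.write_structure(s))
        assert s2 == s

    def test_duplicate_serial_rejected(self):
        text = ("ATOM      1  CA  GLY A   1       1.000   0.000   0.000"
                "  1.00  0.00\n"
                "ATOM      1  CA  GLY A   2       2.000   0.000   0.000"
                "  1.00  0.00\n")
        with pytest.raises(tg.ValidationError, match="duplicate"):
            tg.read_structure(text)

    def test_malformed_coordinate_names_line_number(self):
        text = ("ATOM      1  CA  GLY A   1       1.000   0.000   0.000"
                "  1.00  0.00\n"
                "ATOM      2  CA  GLY A   2       xxxxx   0.000   0.000"
                "  1.00  0.00\n")
        with pytest.raises(tg.PDBParseError, match="line 2"):
            tg.read_structure(text)

    def test_chain_reopened_after_ter_rejected(self):
        text = ("ATOM      1  CA  GLY A   1       1.000   0.000   0.000\n"
                "TER\n"
                "ATOM      2  CA  GLY A   2       2.000   0.000   0.000\n")
        with pytest.raises(tg.ValidationError, match="reopened"):
            tg.read_structure(text)


class TestWriteStructure:
    def test_immobile_flag_in_b_factor_column(self):
        s = make_structure([[0.1, 0.2, 0.3]], mobile=[False])
        line = tg.write_structure(s).splitlines()[0]
        assert line[60:66] == "  1.00"
        s2 = tg.read_structure(tg.write_structure(s))
        assert not s2.mobile[0]

    def test_zero_atom_structure_rejected(self):
        empty = tg.Structure(np.zeros(0, int), np.zeros(0, "U4"),
                             np.zeros(0, int), np.zeros(0, "U3"),
                             np.zeros(0, "U1"), np.zeros((0, 3)),
                             np.zeros(0, bool))
        with pytest.raises(tg.ValidationError):
            tg.write_structure(empty)

    def test_long_atom_name_rejected(self):
        s = make_structure([[0.0, 0.0, 0.0]])
        s.atom_name = np.array(["TOOLG"], dtype="U8")
        with pytest.raises(tg.ValidationError, match="exceeds"):
            tg.write_structure(s)

    def test_biotite_reads_written_pdb_identically(self, full_bundle):
        """Independent parser oracle: biotite must see the same coordinates
        (in Angstrom) and chains that we wrote."""
        biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
        s = full_bundle.post_structure
        text = tg.write_structure(s)
        f = biotite_pdb.PDBFile.read(io.StringIO(text))
        arr = f.get_structure(model=1)
        assert arr.array_length() == s.n_atoms
        np.testing.assert_allclose(arr.coord, s.coords * 10.0, atol=2e-3)
        assert list(np.unique(arr.chain_id)) == sorted(set(s.chain_id))

    @given(st.integers(0, 10_000))
    def test_random_structure_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, n_atoms=12, n_chains=2)
        s2 = tg.read_structure(tg.write_structure(s))
        assert np.array_equal(s2.atom_id, s.atom_id)
        assert np.array_equal(s2.chain_id, s.chain_id)
        assert np.array_equal(s2.mobile, s.mobile)
        # PDB stores 3 decimals in Angstrom: 5e-5 nm
        np.testing.assert_allclose(s2.coords, s.coords, atol=5.1e-5)


def small_trajectory(n_atoms=2, n_frames=3, seed=11):
    rng = np.random.default_rng(seed)
    return tg.Trajectory(
        times=0.1 * np.arange(n_frames),
        frames=rng.random((n_frames, n_atoms, 3)),
        seed=seed, config_digest="abc123", output_stride=50).validate()


class TestTrajectoryContainer:
    def test_roundtrip_precision(self):
        t = small_trajectory()
        buf = io.BytesIO()
        tg.write_trajectory(t, buf)
        buf.seek(0)
        t2 = tg.read_trajectory(buf)
        assert t2.seed == t.seed
        assert t2.config_digest == t.config_digest
        assert t2.output_stride == t.output_stride
        assert np.max(np.abs(t2.frames - t.frames)) < 1e-6
        np.testing.assert_allclose(t2.times, t.times, atol=1e-12)

    def test_every_magic_byte_mutation_rejected(self):
        t = small_trajectory()
        buf = io.BytesIO()
        tg.write_trajectory(t, buf)
        payload = bytearray(buf.getvalue())
        for pos in range(len(MAGIC)):
            mutated = bytearray(payload)
            mutated[pos] ^= 0x01
            with pytest.raises(tg.TrajectoryFormatError):
                tg.read_trajectory(io.BytesIO(bytes(mutated)))

    def test_truncated_payload_reports_frame(self):
        t = small_trajectory(n_frames=3)
        buf = io.BytesIO()
        tg.write_trajectory(t, buf)
        data = buf.getvalue()[:-10]   # cut into the last frame
        with pytest.raises(tg.TrajectoryCorruptionError, match="frame 2"):
            tg.read_trajectory(io.BytesIO(data))

    def test_trailing_garbage_rejected(self):
        t = small_trajectory()
        buf = io.BytesIO()
        tg.write_trajectory(t, buf)
        with pytest.raises(tg.TrajectoryCorruptionError, match="trailing"):
            tg.read_trajectory(io.BytesIO(buf.getvalue() + b"x"))

    def test_run_seed_recorded_in_header(self):
        s, pot = tg.make_harmonic_system(50.0, 2)
        cfg = tg.SimConfig(n_steps=100, output_stride=10, seed=987)
        traj = tg.run_langevin(pot, s, cfg)
        buf = io.BytesIO()
        tg.write_trajectory(traj, buf)
        buf.seek(0)
        assert tg.read_trajectory(buf).seed == 987

    @given(st.integers(0, 10_000))
    def test_random_trajectory_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        t = tg.Trajectory(times=0.05 * np.arange(4),
                          frames=rng.standard_normal((4, 3, 3)),
                          seed=seed, config_digest="d" * int(rng.integers(0, 40)),
                          output_stride=int(rng.integers(1, 100))).validate()
        buf = io.BytesIO()
        tg.write_trajectory(t, buf)
        buf.seek(0)
        t2 = tg.read_trajectory(buf)
        assert np.max(np.abs(t2.frames - t.frames)) < 1e-6
        assert t2.output_stride == t.output_stride
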