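"""Map/structure I/O round trips, vdW assignment and axis finding."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import porelume as pl
from porelume import synthgen as sg
from porelume.structio import (
    DegenerateGeometryError,
    MapFormatError,
    StructureFormatError,
    write_structure,
)

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  O   ALA A   1      13.402   4.712  -4.580  1.00  0.00           O
END
"""


class TestDensityMapIO:
    def test_round_trip_small_map(self, tmp_path):
        dmap = pl.DensityMap(
            values=np.arange(8, dtype=np.float32).reshape(2, 2, 2),
            voxel_size=[1.34, 1.34, 1.34],
            origin=[0.0, 0.0, 0.0],
        )
        pl.write_density_map(dmap, tmp_path / "m.mrc")
        back = pl.read_density_map(tmp_path / "m.mrc")
        np.testing.assert_array_equal(back.values, dmap.values)
        np.testing.assert_allclose(back.voxel_size, dmap.voxel_size, atol=1e-6)
        np.testing.assert_allclose(back.origin, dmap.origin, atol=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_random_values_bitexact(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((16, 16, 16)).astype(np.float32)
        dmap = pl.DensityMap(vals, [1.1, 1.2, 1.3], [-5.0, 2.0, 7.5])
        path = tmp_path_factory.mktemp("rt") / "m.mrc"
        pl.write_density_map(dmap, path)
        back = pl.read_density_map(path)
        np.testing.assert_array_equal(back.values, vals)
        np.testing.assert_allclose(back.origin, dmap.origin, atol=1e-5)

    def test_anisotropic_header_cell(self, tmp_path):
        """Header cell dimensions must equal lattice size times voxel size per axis."""
        import gemmi

        dmap = pl.DensityMap(np.zeros((4, 6, 8), dtype=np.float32),
                             [1.0, 1.5, 2.0], [0, 0, 0])
        pl.write_density_map(dmap, tmp_path / "a.mrc")
        m = gemmi.read_ccp4_map(str(tmp_path / "a.mrc"))
        cell = m.grid.unit_cell.parameters[:3]
        np.testing.assert_allclose(cell, [4 * 1.0, 6 * 1.5, 8 * 2.0], atol=1e-4)

    def test_all_zero_map_statistics(self, tmp_path):
        import gemmi

        dmap = pl.DensityMap(np.zeros((5, 5, 5), dtype=np.float32), [1.34] * 3, [0, 0, 0])
        pl.write_density_map(dmap, tmp_path / "z.mrc")
        m = gemmi.read_ccp4_map(str(tmp_path / "z.mrc"))
        # DMIN, DMAX, DMEAN header words
        assert m.header_float(20) == m.header_float(21) == m.header_float(22) == 0.0

    def test_permuted_axis_order_normalized(self, tmp_path):
        """A file with MAPC/MAPR/MAPS permuted reads back identically to the
        standard-order file (values re-indexed to physical x, y, z)."""
        vals = np.arange(60, dtype=np.float32).reshape(3, 4, 5)
        dmap = pl.DensityMap(vals, [1.1, 1.2, 1.3], [0, 0, 0])
        std_path = tmp_path / "std.mrc"
        pl.write_density_map(dmap, std_path)
        raw = bytearray(std_path.read_bytes())
        nsymbt = struct.unpack_from("<i", raw, 4 * 23)[0]
        off = 1024 + nsymbt

        def set_i(word, v):
            struct.pack_into("<i", raw, 4 * (word - 1), v)

        # file axes (col,row,sec) = (y, z, x): data iterated sec=x slowest,
        # col=y fastest -> C-order of vals transposed to (x, z, y)
        perm_bytes = np.transpose(vals, (0, 2, 1)).astype(np.float32).ravel(order="C").tobytes()
        set_i(1, 4); set_i(2, 5); set_i(3, 3)
        set_i(17, 2); set_i(18, 3); set_i(19, 1)
        raw[off:off + len(perm_bytes)] = perm_bytes
        (tmp_path / "perm.mrc").write_bytes(bytes(raw))

        back = pl.read_density_map(tmp_path / "perm.mrc")
        np.testing.assert_array_equal(back.values, vals)
        np.testing.assert_allclose(back.voxel_size, [1.1, 1.2, 1.3], atol=1e-6)
        # downstream z-profiles are therefore axis-order invariant
        axis = pl.ChannelAxis(point=back.index_to_position((1, 1.5, 0)), direction=(0, 0, 1))
        p_std = pl.axial_density_profile(pl.read_density_map(std_path), axis, column_px=2)
        p_perm = pl.axial_density_profile(back, axis, column_px=2)
        np.testing.assert_array_equal(p_std.mean_density, p_perm.mean_density)

    def test_rejects_non_map_file(self, tmp_path):
        bad = tmp_path / "bad.mrc"
        bad.write_bytes(b"not a map at all" * 10)
        with pytest.raises(MapFormatError):
            pl.read_density_map(bad)

    def test_rejects_nonpositive_voxel(self):
        with pytest.raises(MapFormatError):
            pl.DensityMap(np.zeros((2, 2, 2)), [0.0, 1.0, 1.0], [0, 0, 0])


class TestStructureIO:
    def test_three_atom_pdb_fields(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(THREE_ATOM_PDB)
        model = pl.read_structure(p)
        assert len(model) == 3
        assert [a.element for a in model.atoms] == ["N", "C", "O"]
        np.testing.assert_allclose(model.atoms[1].position, [11.639, 6.071, -5.147])
        assert model.atoms[0].chain_id == "A"
        assert model.atoms[0].residue_name == "ALA"

    def test_pdb_mmcif_cross_format(self, tmp_path):
        """The same model written as PDB and mmCIF reads back identically."""
        import gemmi

        model = sg.make_ideal_helix(10)
        pdb_path = tmp_path / "h.pdb"
        write_structure(model, pdb_path)
        st_ = gemmi.read_structure(str(pdb_path))
        st_.setup_entities()
        cif_path = tmp_path / "h.cif"
        st_.make_mmcif_document().write_file(str(cif_path))
        a = pl.read_structure(pdb_path, format="pdb")
        b = pl.read_structure(cif_path, format="mmcif")
        assert len(a) == len(b)
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-3)

    def test_chain_partition_of_ring(self, ring18):
        assert len(ring18.chains) == 10

    def test_empty_model_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(StructureFormatError):
            pl.read_structure(p)


class TestVdwAssignment:
    def test_direct_lookup(self):
        model = pl.StructureModel([
            sg.AtomRecord(element="C", atom_name="C", chain_id="A",
                          residue_number=i, residue_name="ALA",
                          position=np.array([float(i), 0, 0]))
            for i in range(3)
        ])
        out = pl.assign_vdw_radii(model, {"C": 1.85})
        assert all(a.vdw_radius == 1.85 for a in out.atoms)
        # input untouched
        assert all(np.isnan(a.vdw_radius) for a in model.atoms)

    def test_bundled_table_values(self):
        table = pl.default_vdw_table()
        model = pl.StructureModel([
            sg.AtomRecord(element=el, atom_name=el, chain_id="A",
                          residue_number=i + 1, residue_name="ALA",
                          position=np.array([3.0 * i, 0, 0]))
            for i, el in enumerate(["C", "N", "O"])
        ])
        out = pl.assign_vdw_radii(model)
        assert [a.vdw_radius for a in out.atoms] == [table["C"], table["N"], table["O"]]

    def test_default_fallback(self):
        model = pl.StructureModel([
            sg.AtomRecord(element="C", atom_name="C", chain_id="A",
                          residue_number=1, residue_name="ALA", position=np.zeros(3))
        ])
        out = pl.assign_vdw_radii(model, table={}, default=1.5)
        assert out.atoms[0].vdw_radius == 1.5

    def test_missing_element_raises_with_name(self):
        model = pl.StructureModel([
            sg.AtomRecord(element="XX", atom_name="XX", chain_id="A",
                          residue_number=1, residue_name="UNK", position=np.zeros(3))
        ])
        with pytest.raises(KeyError, match="XX"):
            pl.assign_vdw_radii(model, table={"C": 1.7})


class TestChannelAxis:
    def test_symmetric_ring_axis_is_z(self):
        atoms = []
        for z in (0.0, 40.0):
            for k in range(10):
                ang = 2 * np.pi * k / 10
                atoms.append(sg.AtomRecord(
                    element="C", atom_name="C", chain_id="A",
                    residue_number=len(atoms) + 1, residue_name="ALA",
                    position=np.array([20 * np.cos(ang), 20 * np.sin(ang), z])))
        model = pl.StructureModel(atoms)
        axis = pl.principal_channel_axis(model)
        np.testing.assert_allclose(np.abs(axis.direction), [0, 0, 1], atol=1e-6)
        np.testing.assert_allclose(axis.point[:2], [0, 0], atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_equivariance_under_rigid_motion(self, ring18, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        t = rng.uniform(-30, 30, 3)
        axis0 = pl.principal_channel_axis(ring18)
        axis1 = pl.principal_channel_axis(ring18.transformed(rotation=R, translation=t))
        assert abs(abs(np.dot(axis1.direction, R @ axis0.direction)) - 1) < 1e-6
        np.testing.assert_allclose(axis1.point, R @ axis0.point + t, atol=1e-6)

    def test_self_superposition_under_nfold_rotation(self, ring18):
        axis = pl.principal_channel_axis(ring18, symmetry_order=10)
        assert pl.rotational_symmetry_rmsd(ring18, axis, 10) < 1.0

    def test_collinear_degenerate(self):
        model = pl.StructureModel([
            sg.AtomRecord(element="C", atom_name="C", chain_id="A",
                          residue_number=i + 1, residue_name="ALA",
                          position=np.array([0.0, 0.0, float(i)]))
            for i in range(5)
        ])
        with pytest.raises(DegenerateGeometryError):
            pl.principal_channel_axis(model)
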