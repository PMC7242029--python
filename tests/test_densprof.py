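"""Axial density profiling, exclusion masks and bilayer-peak detection."""

import numpy as np
import pytest

import porelume as pl
from porelume import synthgen as sg
from porelume.structio import AtomRecord, StructureModel

ZAXIS = sg.channel_axis_of()


def flat_map(shape=(24, 24, 40), value=0.0, voxel=1.34):
    n = np.array(shape)
    origin = -(n - 1) * voxel / 2.0
    return pl.DensityMap(np.full(shape, value, dtype=np.float32),
                         [voxel] * 3, origin)


def gaussian_profile_map(centers, sigma=2.0, shape=(24, 24, 60), voxel=1.34):
    dmap = flat_map(shape, 0.0, voxel)
    zs = dmap.origin[2] + np.arange(shape[2]) * voxel
    prof = np.zeros(shape[2])
    for c in centers:
        prof += np.exp(-0.5 * ((zs - c) / sigma) ** 2)
    vals = np.broadcast_to(prof, shape).astype(np.float32)
    return dmap.with_values(vals)


class TestExclusionMask:
    def test_single_atom_sphere_rasterization(self):
        dmap = flat_map((16, 16, 16), voxel=1.0)
        pos = dmap.index_to_position((8, 8, 8))
        model = StructureModel([AtomRecord(
            element="C", atom_name="C", chain_id="A", residue_number=1,
            residue_name="ALA", position=pos, vdw_radius=2.5)])
        mask = pl.build_exclusion_mask(dmap, model, pad=0.0)
        idx = np.argwhere(mask.values)
        pts = dmap.origin + idx * dmap.voxel_size
        d = np.linalg.norm(pts - pos, axis=1)
        assert d.max() <= 2.5 + 1e-9
        # and every voxel within the radius is marked
        all_idx = np.argwhere(~mask.values)
        pts_out = dmap.origin + all_idx * dmap.voxel_size
        assert np.linalg.norm(pts_out - pos, axis=1).min() > 2.5

    def test_empty_model_all_false(self):
        dmap = flat_map()
        mask = pl.build_exclusion_mask(dmap, StructureModel([]), pad=2.0)
        assert not mask.values.any()

    def test_matches_exhaustive_distance_check(self):
        rng = np.random.default_rng(21)
        dmap = flat_map((32, 32, 32), voxel=1.0)
        atoms = [AtomRecord(
            element="C", atom_name="C", chain_id="A", residue_number=i + 1,
            residue_name="ALA",
            position=rng.uniform(-12, 12, 3), vdw_radius=rng.uniform(1.3, 2.4))
            for i in range(20)]
        model = StructureModel(atoms)
        pad = 1.5
        mask = pl.build_exclusion_mask(dmap, model, pad=pad)
        # brute force: every voxel against every atom
        idx = np.indices(dmap.shape).reshape(3, -1).T
        pts = dmap.origin + idx * dmap.voxel_size
        d = np.linalg.norm(pts[:, None, :] - model.coords[None, :, :], axis=2)
        expected = (d <= model.radii[None, :] + pad).any(axis=1).reshape(dmap.shape)
        np.testing.assert_array_equal(mask.values, expected)

    def test_frame_mismatch_error(self):
        dmap = flat_map((8, 8, 8), voxel=1.0)
        far = StructureModel([AtomRecord(
            element="C", atom_name="C", chain_id="A", residue_number=1,
            residue_name="ALA", position=np.array([500.0, 0, 0]), vdw_radius=2.0)])
        with pytest.raises(ValueError, match="outside"):
            pl.build_exclusion_mask(dmap, far, pad=2.0)


class TestAxialProfile:
    def test_constant_map_constant_profile(self):
        dmap = flat_map(value=3.25)
        prof = pl.axial_density_profile(dmap, ZAXIS, column_px=6)
        np.testing.assert_allclose(prof.mean_density, 3.25, atol=1e-6)
        assert len(prof.z) == dmap.shape[2]

    def test_single_slice_indicator(self):
        dmap = flat_map()
        vals = dmap.values.copy()
        vals[:, :, 17] = 1.0
        prof = pl.axial_density_profile(dmap.with_values(vals), ZAXIS, column_px=6)
        assert prof.mean_density[17] == pytest.approx(1.0)
        assert np.count_nonzero(prof.mean_density) == 1

    def test_mean_of_column_linearity(self):
        rng = np.random.default_rng(3)
        a = flat_map().with_values(rng.random((24, 24, 40)).astype(np.float32))
        b = flat_map().with_values(rng.random((24, 24, 40)).astype(np.float32))
        combo = a.with_values(2.0 * a.values + 3.0 * b.values)
        pa = pl.axial_density_profile(a, ZAXIS)
        pb = pl.axial_density_profile(b, ZAXIS)
        pc = pl.axial_density_profile(combo, ZAXIS)
        np.testing.assert_allclose(pc.mean_density,
                                   2.0 * pa.mean_density + 3.0 * pb.mean_density,
                                   rtol=1e-5)

    def test_inplane_90deg_rotation_invariance_exact(self):
        rng = np.random.default_rng(4)
        dmap = flat_map().with_values(rng.random((24, 24, 40)).astype(np.float32))
        rot = dmap.with_values(np.rot90(dmap.values, k=1, axes=(0, 1)).copy())
        p0 = pl.axial_density_profile(dmap, ZAXIS)
        p1 = pl.axial_density_profile(rot, ZAXIS)
        # identical up to float summation order of the permuted column
        np.testing.assert_allclose(p0.mean_density, p1.mean_density, rtol=1e-12)

    def test_whole_voxel_translation_invariance_exact(self):
        rng = np.random.default_rng(5)
        dmap = flat_map().with_values(rng.random((24, 24, 40)).astype(np.float32))
        shifted = pl.DensityMap(dmap.values,
                                dmap.voxel_size,
                                dmap.origin + np.array([2, -1, 0]) * dmap.voxel_size)
        axis2 = pl.ChannelAxis(point=ZAXIS.point + np.array([2, -1, 0]) * dmap.voxel_size,
                               direction=ZAXIS.direction)
        p0 = pl.axial_density_profile(dmap, ZAXIS)
        p1 = pl.axial_density_profile(shifted, axis2)
        np.testing.assert_array_equal(p0.mean_density, p1.mean_density)

    def test_tilted_axis_resampled(self):
        """A slightly conical... no: an axis tilted 30 deg still yields the
        bilayer peak separation after internal resampling."""
        atoms = sg.make_toy_bilayer(sg.BilayerSpec(headgroup_separation=38.0, seed=9))
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("y", 30, degrees=True).as_matrix()
        rot_atoms = [AtomRecord(
            element=a.element, atom_name=a.atom_name, chain_id=a.chain_id,
            residue_number=a.residue_number, residue_name=a.residue_name,
            position=R @ a.position, vdw_radius=a.vdw_radius) for a in atoms]
        spec = pl.RenderSpec(resolution=6.0, pixel=1.34, amplitude_mode="electron-count")
        dmap = pl.simulate_density(rot_atoms, spec)
        axis = pl.ChannelAxis(point=np.array([R @ a.position for a in atoms]).mean(axis=0),
                              direction=R @ np.array([0.0, 0.0, 1.0]))
        prof = pl.axial_density_profile(dmap, axis)
        sig = pl.detect_bilayer_peaks(prof)
        assert sig.separation == pytest.approx(38.0, abs=2.0)

    def test_column_outside_lattice_error(self):
        dmap = flat_map((4, 24, 24))
        with pytest.raises(IndexError):
            pl.axial_density_profile(dmap, ZAXIS, column_px=6)


class TestColumnMaskVerification:
    def test_empty_mask_passes(self):
        dmap = flat_map()
        mask = pl.build_exclusion_mask(dmap, StructureModel([]), pad=2.0)
        report = pl.verify_column_outside_mask(mask, ZAXIS, column_px=6)
        assert report.passed

    def test_on_axis_atom_fails_its_slices(self):
        dmap = flat_map(voxel=1.0)
        r = 3.0
        model = StructureModel([AtomRecord(
            element="C", atom_name="C", chain_id="A", residue_number=1,
            residue_name="ALA", position=np.array([0.0, 0.0, 0.0]), vdw_radius=r)])
        mask = pl.build_exclusion_mask(dmap, model, pad=0.0)
        report = pl.verify_column_outside_mask(mask, ZAXIS, column_px=6)
        assert not report.passed
        overl_z = report.z[report.overlapped]
        assert overl_z.min() >= -r - 1e-9 and overl_z.max() <= r + 1e-9
        # voxel z-centers sit at half-integers, so a radius-3 sphere at z=0
        # covers exactly the 6 slices z in {-2.5, ..., +2.5}
        assert len(overl_z) == 6

    def test_lumen_clears_column(self, ring18):
        """A 6x6 column (half-diagonal 4.02 A at 1.34 A pixels) fits inside
        a 15 A lumen with margin."""
        spec = sg.ChannelSpec(n_subunits=10, lumen_knots=((-20.0, 15.0), (20.0, 15.0)), seed=8)
        model = sg.make_ring_channel(spec)
        dmap = flat_map((48, 48, 40))
        mask = pl.build_exclusion_mask(dmap, model, pad=2.0)
        report = pl.verify_column_outside_mask(mask, ZAXIS, column_px=6)
        assert report.passed


class TestPeakDetection:
    def test_two_gaussians_separation(self):
        # odd slice count puts a lattice plane at z=0 so sampling is symmetric
        dmap = gaussian_profile_map([-19.0, 19.0], shape=(24, 24, 61))
        prof = pl.axial_density_profile(dmap, ZAXIS)
        sig = pl.detect_bilayer_peaks(prof)
        assert sig.n_peaks == 2
        assert sig.separation == pytest.approx(38.0, abs=prof.step / 2 + 1e-9)

    def test_single_gaussian_unimodal(self):
        dmap = gaussian_profile_map([5.0])
        prof = pl.axial_density_profile(dmap, ZAXIS)
        sig = pl.detect_bilayer_peaks(prof)
        assert sig.n_peaks == 1
        assert sig.separation is None

    def test_flat_profile_no_peaks(self):
        prof = pl.AxialDensityProfile(np.arange(20.0), np.ones(20), 6)
        sig = pl.detect_bilayer_peaks(prof)
        assert sig.n_peaks == 0 and sig.separation is None

    def test_scale_invariance(self):
        dmap = gaussian_profile_map([-15.0, 12.0])
        prof = pl.axial_density_profile(dmap, ZAXIS)
        scaled = pl.AxialDensityProfile(prof.z, prof.mean_density * 137.0, 6)
        s0 = pl.detect_bilayer_peaks(prof)
        s1 = pl.detect_bilayer_peaks(scaled)
        np.testing.assert_array_equal(s0.peak_z, s1.peak_z)
        assert s0.separation == s1.separation

    def test_synthetic_bilayer_recovery(self):
        atoms = sg.make_toy_bilayer(sg.BilayerSpec(headgroup_separation=40.0, seed=13))
        spec = pl.RenderSpec(resolution=6.0, pixel=1.34, amplitude_mode="electron-count")
        prof = pl.reference_bilayer_profile(atoms, spec)
        sig = pl.detect_bilayer_peaks(prof)
        assert sig.separation == pytest.approx(40.0, abs=1.34)


class TestCompareProfiles:
    def norm_profile(self, centers):
        dmap = gaussian_profile_map(centers, shape=(24, 24, 70))
        return pl.axial_density_profile(dmap, ZAXIS).normalized()

    def test_identity_all_matched_zero_shift(self):
        a = self.norm_profile([-19.0, 19.0])
        rep = pl.compare_profiles(a, a)
        assert len(rep.matched) == 2
        assert all(m.shift == 0 for m in rep.matched)
        assert not rep.absent_in_a and not rep.absent_in_b

    def test_deleted_peak_reported_absent(self):
        a = self.norm_profile([-19.0, 19.0])
        b = self.norm_profile([19.0])
        rep = pl.compare_profiles(a, b)
        assert len(rep.matched) == 1
        assert rep.absent_in_b == [pytest.approx(-19.0, abs=1.0)]

    def test_requires_normalization(self):
        dmap = gaussian_profile_map([0.0])
        prof = pl.axial_density_profile(dmap, ZAXIS)
        with pytest.raises(ValueError, match="normalized"):
            pl.compare_profiles(prof, prof)

    def test_disjoint_ranges_error(self):
        a = pl.AxialDensityProfile(np.arange(10.0), np.ones(10), 6, "max-1")
        b = pl.AxialDensityProfile(np.arange(20.0, 30.0), np.ones(10), 6, "max-1")
        with pytest.raises(ValueError, match="disjoint"):
            pl.compare_profiles(a, b)
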