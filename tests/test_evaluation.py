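"""Voxelisation, Dice overlap, displacement statistics, mask and VTK I/O."""

import json
import warnings
import xml.etree.ElementTree as ET

import numpy as np
import pytest

import brachysim as bs
from brachysim.errors import GeometryError
from brachysim.evaluation import (dice, inplane_displacement_stats,
                                  prostate_centroid_displacement, voxelize_region)
from brachysim.masks import VoxelMask, read_mask, write_mask
from brachysim.vtkio import export_procedure, write_pvd, write_vtu


@pytest.fixture(scope="module")
def dense_phantom():
    return bs.generate_phantom(bs.PhantomSpec(
        prostate_semi_axes=(20.0, 15.0, 15.0), block_dims=(60, 60, 60),
        nodal_spacing=2.0))


class TestVoxelize:
    def test_ellipsoid_volume_within_five_percent(self, dense_phantom):
        mask = voxelize_region(dense_phantom, None, voxel_size=1.0)
        V = 4.0 / 3.0 * np.pi * 20 * 15 * 15
        assert mask.volume() == pytest.approx(V, rel=0.05)

    def test_rigid_translation_shifts_origin_only(self):
        dom = bs.generate_phantom(bs.PhantomSpec(
            prostate_semi_axes=(20.0, 15.0, 15.0), block_dims=(60, 60, 60),
            nodal_spacing=2.0, jitter=0.2, rng_seed=3))
        a = voxelize_region(dom, None)
        t = np.array([10.0, -5.0, 2.0])
        b = voxelize_region(dom, np.tile(t, (dom.n_nodes, 1)))
        assert np.array_equal(a.data, b.data)
        assert np.allclose(b.origin - a.origin, t)

    def test_volume_stable_under_voxel_refinement(self):
        dom = bs.generate_phantom(bs.PhantomSpec(
            prostate_semi_axes=(12.0, 9.0, 9.0), block_dims=(30, 30, 30),
            nodal_spacing=1.0))
        coarse = voxelize_region(dom, None, voxel_size=1.0)
        fine = voxelize_region(dom, None, voxel_size=0.5)
        assert abs(fine.volume() - coarse.volume()) / coarse.volume() < 0.02

    def test_degenerate_point_set_raises_geometry_error(self, dense_phantom):
        coplanar = dense_phantom
        u = -coplanar.node_coords.copy()
        u[:, :2] = 0.0  # squash everything onto a plane
        with pytest.raises(GeometryError):
            voxelize_region(coplanar, u)


class TestDice:
    @staticmethod
    def _random_mask(rng, shape=(12, 12, 12)):
        return VoxelMask(rng.random(shape) < 0.35, origin=(0, 0, 0), voxel_size=1.0)

    def test_identity_and_disjoint(self, rng):
        a = self._random_mask(rng)
        assert dice(a, a) == 1.0
        b = VoxelMask(~a.data, origin=a.origin, voxel_size=1.0)
        assert dice(a, b) == 0.0

    def test_matches_brute_force_counting_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = self._random_mask(rng)
            b = self._random_mask(rng)
            expected = 2.0 * np.sum(a.data & b.data) / (a.data.sum() + b.data.sum())
            assert dice(a, b) == expected

    def test_symmetry(self, rng):
        a = self._random_mask(rng)
        b = self._random_mask(rng)
        assert dice(a, b) == dice(b, a)

    def test_erosion_monotone(self, rng):
        from scipy import ndimage

        a = VoxelMask(np.ones((10, 10, 10), dtype=bool))
        eroded1 = VoxelMask(ndimage.binary_erosion(a.data))
        eroded2 = VoxelMask(ndimage.binary_erosion(eroded1.data))
        assert dice(a, a) >= dice(a, eroded1) >= dice(a, eroded2)

    def test_both_empty_is_one_with_warning(self):
        e = VoxelMask(np.zeros((4, 4, 4), dtype=bool))
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            assert dice(e, e) == 1.0
        assert len(w) == 1

    def test_resampling_handles_different_grids(self, rng):
        a = self._random_mask(rng, (16, 16, 16))
        # same occupancy expressed on a coarser shifted grid overlaps imperfectly
        b = VoxelMask(a.data[::2, ::2, ::2], origin=(0.0, 0.0, 0.0), voxel_size=2.0)
        d = dice(a, b)
        assert 0.0 < d < 1.0


class TestCompareSnapshots:
    @pytest.fixture(scope="class")
    def still_procedure(self):
        from brachysim.insertion import InsertionConfig, SolverConfig, run_procedure

        dom = bs.generate_phantom(bs.PhantomSpec(
            prostate_semi_axes=(12.0, 9.0, 9.0), block_dims=(33, 33, 33),
            nodal_spacing=3.0))
        return run_procedure(dom, bs.NeedlePlan([]), InsertionConfig(),
                             SolverConfig(max_iter=100))

    def test_same_event_has_perfect_overlap(self, still_procedure):
        from brachysim.evaluation import compare_snapshots

        assert compare_snapshots(still_procedure, ("initial", "initial")) == 1.0

    def test_missing_event_raises_lookup_error(self, still_procedure):
        from brachysim.evaluation import compare_snapshots

        with pytest.raises(KeyError):
            compare_snapshots(still_procedure, ("initial", "catheter_5"))


class TestDiceProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 2**16), frac=st.floats(0.05, 0.9))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dice_bounds_and_symmetry(self, seed, frac):
        r = np.random.default_rng(seed)
        a = VoxelMask(r.random((6, 6, 6)) < frac)
        b = VoxelMask(r.random((6, 6, 6)) < frac)
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        assert dice(a, a) == 1.0


class TestDisplacementStats:
    def test_zero_field(self, dense_phantom):
        s = inplane_displacement_stats(np.zeros((dense_phantom.n_nodes, 3)),
                                       dense_phantom)
        assert s.mean == s.sd == s.max == 0.0

    def test_out_of_plane_displacement_is_invisible(self, dense_phantom):
        u = np.tile([0.0, 0.0, 4.2], (dense_phantom.n_nodes, 1))
        s = inplane_displacement_stats(u, dense_phantom, plane_normal=(0, 0, 1))
        assert s.mean == pytest.approx(0.0, abs=1e-12)
        assert s.max == pytest.approx(0.0, abs=1e-12)

    def test_uniform_inplane_displacement(self, dense_phantom):
        u = np.tile([3.0, 4.0, 0.0], (dense_phantom.n_nodes, 1))
        s = inplane_displacement_stats(u, dense_phantom, plane_normal=(0, 0, 1))
        assert s.mean == pytest.approx(5.0)
        assert s.max == pytest.approx(5.0)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_centroid_displacement(self, dense_phantom):
        u = np.tile([0.0, 0.0, 1.5], (dense_phantom.n_nodes, 1))
        assert np.allclose(prostate_centroid_displacement(u, dense_phantom),
                           [0, 0, 1.5])


class TestMaskIO:
    def _mask(self):
        rng = np.random.default_rng(5)
        return VoxelMask(rng.random((8, 9, 10)) < 0.4, origin=(1.0, -2.0, 3.0),
                         voxel_size=1.5)

    @pytest.mark.parametrize("ext", ["nii.gz", "mha"])
    def test_roundtrip(self, tmp_path, ext):
        m = self._mask()
        path = tmp_path / f"mask.{ext}"
        write_mask(path, m)
        back = read_mask(path)
        assert np.array_equal(back.data, m.data)
        assert back.voxel_size == pytest.approx(m.voxel_size)
        assert np.allclose(back.origin, m.origin)

    def test_mask_invariants(self):
        with pytest.raises(Exception):
            VoxelMask(np.zeros((3, 3), dtype=bool))  # not 3D
        with pytest.raises(Exception):
            VoxelMask(np.zeros((3, 3, 3), dtype=bool), voxel_size=0.0)


class TestVTKAndPipeline:
    def test_vtu_is_valid_xml_with_expected_points(self, tmp_path, rng):
        pts = rng.normal(size=(17, 3))
        path = tmp_path / "cloud.vtu"
        write_vtu(path, pts, {"displacement": np.zeros((17, 3)),
                              "region": np.zeros(17)})
        root = ET.parse(path).getroot()
        piece = root.find(".//Piece")
        assert piece.get("NumberOfPoints") == "17"

    def test_procedure_export_writes_series_and_log(self, tmp_path):
        dom = bs.generate_phantom(bs.PhantomSpec(
            prostate_semi_axes=(12.0, 9.0, 9.0), block_dims=(33, 33, 33),
            nodal_spacing=3.0))
        plan = bs.NeedlePlan([])
        from brachysim.insertion import InsertionConfig, SolverConfig, run_procedure

        res = run_procedure(dom, plan, InsertionConfig(), SolverConfig(max_iter=100))
        export_procedure(res, tmp_path, basename="run")
        assert (tmp_path / "run.pvd").exists()
        assert (tmp_path / "run_000.vtu").exists()
        log = json.loads((tmp_path / "events.json").read_text())
        assert log[0]["event"] == "initial"

    def test_pvd_collection(self, tmp_path):
        path = tmp_path / "series.pvd"
        write_pvd(path, [(0, "a.vtu"), (1, "b.vtu")])
        root = ET.parse(path).getroot()
        assert len(root.findall(".//DataSet")) == 2
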