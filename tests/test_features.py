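"""Morphometric features: region properties, neighbor distances and
Fourier boundary descriptors."""

import numpy as np
import pytest

import filamorph as fm
from filamorph import features as feat
from filamorph import segmentation as seg

from conftest import disk_mask


def obj_from_mask(mask, object_id=1, intensities=None):
    pix = np.column_stack(np.nonzero(mask))
    boundary = seg.trace_boundary(pix)
    inten = (np.full(len(pix), 100.0) if intensities is None
             else np.asarray(intensities, dtype=float))
    return seg.StructureObject(object_id=object_id, pixels=pix,
                               boundary=boundary, area=len(pix),
                               intensities=inten)


class TestRegionFeatures:
    def test_solid_square(self):
        m = np.ones((20, 20), dtype=bool)
        f = feat.region_features(obj_from_mask(m))
        assert f["Area"] == 400
        assert f["FilledArea"] == 400
        assert f["Extent"] == 1.0
        assert f["Solidity"] == 1.0

    def test_square_with_hole(self):
        m = np.ones((20, 20), dtype=bool)
        m[10, 10] = False
        f = feat.region_features(obj_from_mask(m))
        assert f["Area"] == 399
        assert f["FilledArea"] == 400

    def test_digital_disk(self):
        f = feat.region_features(obj_from_mask(disk_mask(10)))
        assert f["Eccentricity"] < 0.1
        assert f["EquivDiameter"] == pytest.approx(
            2.0 * np.sqrt(f["Area"] / np.pi))

    def test_single_pixel_ellipse_convention(self):
        f = feat.region_features(obj_from_mask(np.ones((1, 1), dtype=bool)))
        assert f["MajorAxisLength"] == pytest.approx(2.0 / np.sqrt(3.0))
        assert f["MajorAxisLength"] == f["MinorAxisLength"]
        assert f["Eccentricity"] == 0.0

    def test_eccentricity_strictly_below_one(self):
        m = np.zeros((1, 12), dtype=bool)
        m[0, :] = True                    # 1-px-wide line
        f = feat.region_features(obj_from_mask(m))
        assert 0.9 < f["Eccentricity"] < 1.0


class TestNeighborDistances:
    def test_two_point_objects_five_apart(self):
        a = seg.StructureObject(1, np.array([[10, 10]]),
                                np.array([[10.0, 10.0]]), 1,
                                intensities=np.array([5.0]))
        b = seg.StructureObject(2, np.array([[10, 15]]),
                                np.array([[10.0, 15.0]]), 1,
                                intensities=np.array([5.0]))
        f = feat.neighbor_distance_features(a, [a, b], (30, 30))
        assert f["NeighborDistMean"] == pytest.approx(5.0)
        assert f["NeighborDistSD"] == pytest.approx(0.0)

    def test_uniform_intensity_sd_zero(self):
        o = obj_from_mask(disk_mask(3), intensities=None)
        f = feat.neighbor_distance_features(o, [o], (20, 20))
        assert f["IntensitySD"] == 0.0

    def test_lone_object_uses_sentinel(self):
        dist_map, lone = feat.neighbor_distance_map([obj_from_mask(
            disk_mask(3))], 0, (30, 40))
        assert lone
        assert np.allclose(dist_map, np.hypot(30, 40))


class TestFourierShape:
    def circle_boundary(self, r, n=10000, center=(50.0, 50.0)):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        # counter-clockwise in the (x, y) = (col, row) frame
        return np.column_stack([center[0] + r * np.sin(th),
                                center[1] + r * np.cos(th)])

    def test_circle_energy_in_first_mode(self):
        r = 5.0
        amps, err = feat.fourier_shape_features(self.circle_boundary(r), 30)
        assert amps[0] == pytest.approx(r, abs=1e-6)      # |c(+1)|
        assert np.max(amps[1:]) < 1e-6 * r
        assert err < 1e-6

    def test_rotation_invariance_of_amplitudes(self):
        rng = np.random.default_rng(1)
        m = disk_mask(6)
        m[2:5, 2:9] = True
        a0, _ = feat.fourier_shape_features(
            seg.trace_boundary(np.column_stack(np.nonzero(m))), 30)
        a90, _ = feat.fourier_shape_features(
            seg.trace_boundary(np.column_stack(np.nonzero(np.rot90(m)))), 30)
        np.testing.assert_allclose(a0, a90, rtol=1e-9, atol=1e-9)

    def test_exclusion_flag_follows_reconstruction_error(self):
        # a long thin object cannot be reconstructed to 0.1 px by the
        # truncated series; a small disk can
        from scipy import ndimage
        from skimage.morphology import disk as _disk
        zig = np.zeros((40, 70), dtype=bool)   # jagged thin polyline
        r = 5
        for c in range(2, 62):
            r += 1 if (c // 10) % 2 == 0 else -1
            zig[r, c] = True
        zig = ndimage.binary_dilation(zig, structure=_disk(1))
        fr = seg.ImageFrame(np.zeros((80, 80)), 0.1)
        objs = [obj_from_mask(zig), ]
        fmx = feat.compute_frame_features(objs, fr)
        assert fmx.meta.loc[0, "boundary_err"] > 0.1
        assert bool(fmx.meta.loc[0, "excluded"])
        fmx2 = feat.compute_frame_features([obj_from_mask(disk_mask(3))], fr)
        assert fmx2.meta.loc[0, "boundary_err"] <= 0.1
        assert not bool(fmx2.meta.loc[0, "excluded"])

    def test_short_boundary_fallback(self):
        amps, err = feat.fourier_shape_features(np.array([[3.0, 3.0]]), 30)
        assert err == 0.0
        assert np.all(amps == 0.0)

    def test_disk_first_amplitude_scales_linearly_with_radius(self):
        radii = np.arange(5, 21)
        c1 = []
        for r in radii:
            b = seg.trace_boundary(np.column_stack(np.nonzero(disk_mask(r))))
            amps, _ = feat.fourier_shape_features(b, 30)
            c1.append(amps[0])
        slope = np.polyfit(radii, c1, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.01)


class TestFourierDistance:
    def test_constant_profile(self):
        amps = feat.fourier_distance_features(np.full(128, 7.5), 30)
        assert amps[0] == pytest.approx(7.5)
        assert np.max(amps[1:]) < 1e-12

    def test_cosine_profile_single_mode(self):
        s = np.arange(128)
        amps = feat.fourier_distance_features(np.cos(2 * np.pi * s / 128),
                                              30)
        assert amps[1] == pytest.approx(0.5, abs=1e-12)
        others = np.delete(amps, 1)
        assert np.max(np.abs(others)) < 1e-12

    def test_matches_bruteforce_profile(self):
        # distances computed point-by-point against the other object's
        # pixels, independently of the distance-transform path
        a = obj_from_mask(disk_mask(5))
        bpix = np.column_stack(np.nonzero(disk_mask(3))) + [30, 5]
        b = seg.StructureObject(2, bpix, seg.trace_boundary(bpix),
                                len(bpix), intensities=np.ones(len(bpix)))
        shape = (60, 60)
        dist_map, _ = feat.neighbor_distance_map([a, b], 0, shape)
        pts = feat.resample_boundary(a.boundary, 128)
        from scipy import ndimage
        profile = ndimage.map_coordinates(dist_map, [pts[:, 0], pts[:, 1]],
                                          order=1, mode="nearest")
        brute = np.array([np.min(np.hypot(p[0] - bpix[:, 0],
                                          p[1] - bpix[:, 1]))
                          for p in pts])
        assert np.max(np.abs(profile - brute)) < 0.1
        np.testing.assert_allclose(
            feat.fourier_distance_features(profile, 30),
            feat.fourier_distance_features(brute, 30), atol=0.05)


class TestStandardize:
    def matrix(self, X):
        import pandas as pd
        df = pd.DataFrame(np.asarray(X, dtype=float))
        df.columns = [f"f{i}" for i in range(df.shape[1])]
        meta = pd.DataFrame({"image_id": ["i"] * len(df),
                             "object_id": range(len(df)),
                             "area": np.ones(len(df)),
                             "excluded": [False] * len(df)})
        return feat.FeatureMatrix(features=df, meta=meta)

    def test_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        std = feat.standardize(self.matrix(rng.normal(5, 3, (40, 6))))
        assert np.abs(std.features.mean()).max() < 1e-9
        assert np.abs(std.features.std(ddof=0) - 1).max() < 1e-9

    def test_constant_column_dropped(self, caplog):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with caplog.at_level("WARNING", logger="filamorph.features"):
            std = feat.standardize(self.matrix(X))
        assert list(std.features.columns) == ["f0"]
        assert "zero-variance" in caplog.text

    def test_reapplying_parameters_is_bitwise_identical(self):
        rng = np.random.default_rng(1)
        fmx = self.matrix(rng.normal(0, 2, (25, 4)))
        std = feat.standardize(fmx)
        again = feat.apply_standardization(fmx, std.means, std.sds)
        assert (std.features.to_numpy() == again.features.to_numpy()).all()

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            feat.standardize(self.matrix(np.ones((1, 3))))


class TestInvariances:
    def test_translation_invariance_exact(self):
        base = np.zeros((80, 80))
        base[10:16, 10:20] = 4000
        base[40:44, 40:44] = 4000
        shifted = np.roll(np.roll(base, 7, axis=0), 3, axis=1)
        rows = []
        for img in (base, shifted):
            fr = seg.ImageFrame(img, 0.1)
            mask = seg.CellMask(np.ones_like(img, dtype=bool), 1.0)
            objs = seg.segment_structures(fr, mask, 2000.0)
            fmx = feat.compute_frame_features(objs, fr)
            rows.append(fmx.features.sort_values("Area").to_numpy())
        np.testing.assert_array_equal(rows[0], rows[1])

    def test_rotation_invariance_of_full_vector(self):
        # 90-degree frame rotation: region and shape blocks agree to 1e-6
        base = np.zeros((80, 80))
        base[10:16, 10:26] = 4000
        base[40:46, 40:46] = 4000
        rot = np.rot90(base).copy()
        rows = []
        for img in (base, rot):
            fr = seg.ImageFrame(img, 0.1)
            mask = seg.CellMask(np.ones_like(img, dtype=bool), 1.0)
            objs = seg.segment_structures(fr, mask, 2000.0)
            fmx = feat.compute_frame_features(objs, fr)
            cols = feat.REGION_FEATURES + feat.shape_feature_names(30)
            rows.append(fmx.features.sort_values("Area")[cols].to_numpy())
        np.testing.assert_allclose(rows[0], rows[1], rtol=1e-6, atol=1e-6)

    def test_excluded_fraction_small_on_default_scenes(self, segmented_scene):
        scene, frame, mask, bgsub, objects = segmented_scene
        fmx = feat.compute_frame_features(objects, bgsub)
        assert fmx.meta.excluded.mean() < 0.01 or fmx.meta.excluded.sum() <= 1
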