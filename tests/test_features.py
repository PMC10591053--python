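"""Feature extraction: shape, stains, intensity, smoothing, texture."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon
from shapely import affinity

from mesograph.features import (DEEP_EMBEDDING_DIM, HARALICK_STAT_NAMES,
                                INTENSITY_NAMES, SHAPE_NAMES, Standardizer,
                                assemble_feature_matrix, canonical_schema,
                                compute_core_features,
                                delaunay_cluster_features, deep_features,
                                haralick_features, haralick_from_glcm,
                                intensity_features, shape_features,
                                smooth_features)
from mesograph.graphs import delaunay_adjacency
from mesograph.stains import (HE_STAIN_MATRIX, StainChannels,
                              optical_density, recompose_od,
                              stain_deconvolve)


def circle_polygon(r=10.0, n=256, cx=0.0, cy=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + r * np.cos(t),
                                    cy + r * np.sin(t)]))


def ellipse_polygon(a, b, n=512):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([a * np.cos(t), b * np.sin(t)]))


class TestShapeFeatures:
    def test_circle_limit(self):
        circle = circle_polygon(r=10.0)
        f = shape_features(circle, circle_polygon(r=12.0))
        assert f["nucleus_circularity"] >= 0.999
        assert f["nucleus_max_caliper"] == pytest.approx(20.0, abs=0.01)
        assert f["nucleus_min_caliper"] == pytest.approx(20.0, abs=0.01)

    def test_elongated_ellipse_against_perimeter_oracle(self):
        a, b = 20.0, 5.0
        ellipse = ellipse_polygon(a, b)
        # fine numeric perimeter integration, independent of shapely
        t = np.linspace(0, 2 * np.pi, 20001)
        x, y = a * np.cos(t), b * np.sin(t)
        perim = np.hypot(np.diff(x), np.diff(y)).sum()
        expected = 4 * math.pi * (math.pi * a * b) / perim**2
        f = shape_features(ellipse, ellipse.buffer(1.0))
        assert f["nucleus_circularity"] == pytest.approx(expected,
                                                         rel=1e-3)

    def test_unit_square_closed_form(self):
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        f = shape_features(square, square.buffer(0.5))
        assert f["nucleus_area"] == pytest.approx(1.0)
        assert f["nucleus_perimeter"] == pytest.approx(4.0)
        assert f["nucleus_circularity"] == pytest.approx(math.pi / 4)
        assert f["nucleus_max_caliper"] == pytest.approx(math.sqrt(2))
        assert f["nucleus_min_caliper"] == pytest.approx(1.0)

    def test_rigid_motion_and_vertex_roll_invariance(self):
        ellipse = ellipse_polygon(8.0, 3.0, n=128)
        ref = shape_features(ellipse, ellipse.buffer(1.0))
        moved = affinity.rotate(affinity.translate(ellipse, 40.0, -7.0),
                                33.0, origin="centroid")
        coords = np.asarray(moved.exterior.coords)[:-1]
        rolled = Polygon(np.roll(coords, 17, axis=0))
        f = shape_features(rolled, rolled.buffer(1.0))
        for k in ("nucleus_area", "nucleus_perimeter",
                  "nucleus_circularity", "nucleus_max_caliper",
                  "nucleus_min_caliper"):
            assert f[k] == pytest.approx(ref[k], abs=1e-6)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(Exception):
            shape_features(Polygon([(0, 0), (1, 0), (1, 0)]),
                           circle_polygon())


class TestStainDeconvolution:
    def test_white_pixel_zero_od(self):
        white = np.full((1, 1, 3), 255, dtype=np.uint8)
        ch = stain_deconvolve(white)
        assert ch.hematoxylin[0, 0] == pytest.approx(0.0, abs=2e-3)
        assert ch.eosin[0, 0] == pytest.approx(0.0, abs=2e-3)
        assert ch.od_sum[0, 0] == pytest.approx(0.0, abs=5e-3)

    def test_pixel_on_hematoxylin_vector_has_no_eosin(self):
        c = 0.7
        rgb = np.clip(256.0 * 10 ** (-c * HE_STAIN_MATRIX[0]) - 1.0,
                      0, 255)
        od = optical_density(rgb.reshape(1, 1, 3))
        conc = od.reshape(3) @ np.linalg.inv(HE_STAIN_MATRIX)
        ch = stain_deconvolve(rgb.reshape(1, 1, 3))
        # quantisation to integers moves the pixel slightly off the ray
        assert ch.hematoxylin[0, 0] == pytest.approx(conc[0], abs=1e-9)
        assert ch.eosin[0, 0] < 0.02

    def test_deconvolve_recompose_round_trip(self):
        rng = np.random.default_rng(0)
        conc = rng.uniform(0.05, 0.8, (6, 6, 3))
        od = recompose_od(conc)
        flat = od.reshape(-1, 3) @ np.linalg.inv(HE_STAIN_MATRIX)
        assert np.abs(flat.reshape(6, 6, 3) - conc).max() < 1e-6

    def test_singular_matrix_rejected(self):
        bad = np.vstack([HE_STAIN_MATRIX[0], HE_STAIN_MATRIX[0]])
        with pytest.raises(ValueError):
            stain_deconvolve(np.zeros((2, 2, 3), dtype=np.uint8), bad)


def _channels(h, e=None):
    h = np.asarray(h, dtype=float)
    e = h if e is None else np.asarray(e, dtype=float)
    return StainChannels(hematoxylin=h, eosin=e, od_sum=h + e)


class TestIntensityFeatures:
    def test_constant_channel(self):
        h = np.full((5, 5), 0.7)
        nuc = np.zeros((5, 5), bool)
        nuc[1:3, 1:3] = True
        cell = np.zeros((5, 5), bool)
        cell[0:4, 0:4] = True
        f = intensity_features(_channels(h), nuc, cell)
        for comp in ("nucleus", "cytoplasm", "cell"):
            assert f[f"h_mean_{comp}"] == pytest.approx(0.7)
            assert f[f"h_median_{comp}"] == pytest.approx(0.7)
            assert f[f"h_sd_{comp}"] == pytest.approx(0.0)

    def test_two_pixel_population_sd(self):
        h = np.array([[0.0, 2.0]])
        mask = np.ones((1, 2), bool)
        f = intensity_features(_channels(h), mask, mask)
        assert f["h_mean_nucleus"] == pytest.approx(1.0)
        assert f["h_median_nucleus"] == pytest.approx(1.0)
        assert f["h_sd_nucleus"] == pytest.approx(1.0)  # ddof=0

    def test_matches_brute_force_statistics(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(0, 1, (8, 8))
        e = rng.uniform(0, 1, (8, 8))
        nuc = rng.random((8, 8)) < 0.3
        nuc[0, 0] = True
        cell = nuc | (rng.random((8, 8)) < 0.3)
        f = intensity_features(_channels(h, e), nuc, cell)
        cyto = cell & ~nuc
        for stain, img in (("h", h), ("e", e)):
            for comp, mask in (("nucleus", nuc), ("cytoplasm", cyto),
                               ("cell", cell)):
                vals = sorted(img[r, c] for r in range(8) for c in range(8)
                              if mask[r, c])
                assert f[f"{stain}_mean_{comp}"] == pytest.approx(
                    sum(vals) / len(vals))
                assert f[f"{stain}_sd_{comp}"] == pytest.approx(
                    math.sqrt(sum((v - sum(vals) / len(vals))**2
                                  for v in vals) / len(vals)))

    def test_empty_cytoplasm_sentinel(self):
        h = np.full((3, 3), 0.5)
        mask = np.ones((3, 3), bool)
        f = intensity_features(_channels(h), mask, mask)
        assert f["h_mean_cytoplasm"] == 0.0
        assert f["cytoplasm_empty"] == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intensity_features(_channels(np.ones((3, 3))),
                               np.ones((2, 2), bool), np.ones((2, 2), bool))


class TestSmoothFeatures:
    def test_isolated_cell_keeps_own_values(self):
        cents = np.array([[0.0, 0.0], [1000.0, 1000.0]])
        base = pd.DataFrame({"f": [3.0, 9.0]})
        out = smooth_features(cents, base)
        assert out["smoothed_f"].tolist() == [3.0, 9.0]
        assert out["nearby_detection_count"].tolist() == [0, 0]

    def test_constant_field_idempotent(self):
        rng = np.random.default_rng(1)
        cents = rng.uniform(0, 60, (20, 2))
        base = pd.DataFrame({"f": np.full(20, 4.2)})
        out = smooth_features(cents, base)
        assert np.allclose(out["smoothed_f"], 4.2)

    def test_two_cell_hand_computed_gaussian(self):
        cents = np.array([[0.0, 0.0], [10.0, 0.0]])
        base = pd.DataFrame({"f": [0.0, 1.0]})
        out = smooth_features(cents, base, kernel_diameter=50.0)
        w = math.exp(-0.5 * (10.0 / 12.5) ** 2)
        assert out["smoothed_f"].iloc[0] == pytest.approx(w / (1 + w))
        assert out["smoothed_f"].iloc[1] == pytest.approx(1 / (1 + w))
        assert out["nearby_detection_count"].tolist() == [1, 1]

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(3)
        cents = rng.uniform(0, 100, (40, 2))
        base = pd.DataFrame({"f": rng.normal(size=40)})
        out = smooth_features(cents, base)
        assert (out["smoothed_f"] >= base["f"].min() - 1e-12).all()
        assert (out["smoothed_f"] <= base["f"].max() + 1e-12).all()


class TestDelaunayClusterFeatures:
    def test_triangle_neighbor_counts(self):
        cents = np.array([[0., 0.], [10., 0.], [5., 8.]])
        base = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        out = delaunay_cluster_features(delaunay_adjacency(cents), base)
        assert out["delaunay_neighbor_count"].tolist() == [2, 2, 2]
        assert np.allclose(out["cluster_mean_f"], 2.0)

    def test_matches_brute_force_neighbor_means(self):
        rng = np.random.default_rng(5)
        cents = rng.uniform(0, 100, (20, 2))
        base = pd.DataFrame({"a": rng.normal(size=20),
                             "b": rng.normal(size=20)})
        adj = delaunay_adjacency(cents)
        out = delaunay_cluster_features(adj, base)
        for i in range(20):
            members = [i] + list(adj.neighbors[i])
            for col in ("a", "b"):
                expected = np.mean([base[col].iloc[j] for j in members])
                assert out[f"cluster_mean_{col}"].iloc[i] == \
                    pytest.approx(expected)

    def test_collinear_fallback_flagged(self):
        cents = np.array([[0., 0.], [10., 0.], [20., 0.]])
        base = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        out = delaunay_cluster_features(
            delaunay_adjacency(cents, fallback_radius=15.0), base)
        assert out.attrs["delaunay_fallback"]
        assert out["delaunay_neighbor_count"].iloc[1] == 2


def oracle_haralick(patch, mask, n_levels):
    """Pure-Python co-occurrence enumeration and textbook statistics."""
    vals = [patch[r][c] for r in range(patch.shape[0])
            for c in range(patch.shape[1]) if mask[r][c]]
    lo, hi = min(vals), max(vals)
    levels = {}
    for r in range(patch.shape[0]):
        for c in range(patch.shape[1]):
            if hi > lo:
                levels[(r, c)] = min(n_levels - 1,
                                     int((patch[r][c] - lo) / (hi - lo)
                                         * n_levels))
            else:
                levels[(r, c)] = 0
    glcm = [[0.0] * n_levels for _ in range(n_levels)]
    for (dr, dc) in ((0, 1), (1, 0), (1, 1), (1, -1)):
        for r in range(patch.shape[0]):
            for c in range(patch.shape[1]):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < patch.shape[0] and 0 <= c2 < patch.shape[1] \
                        and mask[r][c] and mask[r2][c2]:
                    a, b = levels[(r, c)], levels[(r2, c2)]
                    glcm[a][b] += 1
                    glcm[b][a] += 1
    total = sum(map(sum, glcm))
    return np.array(glcm) / total


class TestHaralickFeatures:
    def test_constant_region_degenerate_glcm(self):
        patch = np.full((9, 9), 0.4)
        mask = np.ones((9, 9), bool)
        f = haralick_features(patch, mask)
        assert f["asm"] == pytest.approx(1.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["correlation"] == 0.0  # stated zero-variance convention

    def test_checkerboard_contrast_hand_value(self):
        patch = np.indices((6, 6)).sum(axis=0) % 2
        mask = np.ones((6, 6), bool)
        f = haralick_features(patch.astype(float), mask, n_levels=2)
        # horizontal+vertical pairs all differ, diagonals all match:
        # unequal mass 120 / total 220 -> contrast 6/11
        assert f["contrast"] == pytest.approx(6.0 / 11.0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        patch = rng.uniform(0, 1, (12, 12))
        yy, xx = np.mgrid[:12, :12]
        mask = (yy - 5.5) ** 2 + (xx - 5.5) ** 2 <= 25
        f = haralick_features(patch, mask, n_levels=8)
        glcm = oracle_haralick(patch, mask, 8)
        expected = haralick_from_glcm(glcm)
        for name in HARALICK_STAT_NAMES:
            assert f[name] == pytest.approx(expected[name], abs=1e-6), name

    def test_region_outside_image_rejected(self):
        with pytest.raises(ValueError):
            haralick_features(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestDeepFeatures:
    def test_default_backbone_length(self):
        patch = np.random.default_rng(0).integers(
            0, 255, (72, 72, 3)).astype(np.uint8)
        vec = deep_features(patch)
        assert vec.shape == (DEEP_EMBEDDING_DIM,)
        assert DEEP_EMBEDDING_DIM == 512

    def test_deterministic(self):
        patch = np.random.default_rng(1).integers(
            0, 255, (72, 72, 3)).astype(np.uint8)
        assert np.array_equal(deep_features(patch), deep_features(patch))

    def test_none_backbone_disables_group(self):
        patch = np.zeros((72, 72, 3), dtype=np.uint8)
        assert deep_features(patch, backbone="none") is None
        assert not any(g == "deep"
                       for g in canonical_schema(False).groups)

    def test_wrong_geometry_rejected(self):
        with pytest.raises(ValueError):
            deep_features(np.zeros((64, 64, 3), dtype=np.uint8))


class TestSchemaAndAssembly:
    def test_canonical_counts(self):
        assert len(SHAPE_NAMES) == 10
        assert len(INTENSITY_NAMES) == 18
        schema = canonical_schema(include_deep=False)
        assert len(schema) == 129
        assert len(canonical_schema(include_deep=True)) == 129 + 512

    def test_group_subset_assembly(self):
        schema = canonical_schema(False)
        shape_only = tuple(e for e in schema.entries if e[1] == "shape")
        from mesograph.features import FeatureSchema
        sub = FeatureSchema(shape_only)
        table = pd.DataFrame(np.ones((3, 10)), columns=SHAPE_NAMES)
        out = assemble_feature_matrix({"shape": table}, sub)
        assert out.shape == (3, 10)
        with pytest.raises(ValueError):
            assemble_feature_matrix({"shape": table}, schema)

    def test_standardize_round_trip(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(rng.normal(2.0, 3.0, (30, 4)),
                             columns=list("abcd"))
        std = Standardizer().fit([table])
        back = std.inverse_transform(std.transform(table))
        assert np.abs(back.to_numpy() - table.to_numpy()).max() < 1e-10

    def test_full_pipeline_feature_table(self, biphasic_detections,
                                         biphasic_image):
        table = compute_core_features(biphasic_detections, biphasic_image,
                                      mpp=1.0)
        assert list(table.columns) == canonical_schema(False).names
        assert np.isfinite(table.to_numpy()).all()

    def test_features_invariant_to_cell_ordering(self,
                                                 biphasic_detections,
                                                 biphasic_image):
        ref = compute_core_features(biphasic_detections, biphasic_image,
                                    mpp=1.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(biphasic_detections))
        shuffled = biphasic_detections.iloc[perm].reset_index(drop=True)
        out = compute_core_features(shuffled, biphasic_image, mpp=1.0)
        assert np.allclose(out.to_numpy(),
                           ref.to_numpy()[perm], atol=1e-9)

    def test_sarcomatoid_cells_larger_and_more_elongated(
            self, biphasic_detections, biphasic_image):
        table = compute_core_features(biphasic_detections, biphasic_image,
                                      mpp=1.0)
        sar = (biphasic_detections["planted_class"]
               == "sarcomatoid").to_numpy()
        assert table["nucleus_area"][sar].mean() > \
            table["nucleus_area"][~sar].mean()
        elongation = table["nucleus_max_caliper"] / \
            table["nucleus_min_caliper"]
        assert elongation[sar].mean() > elongation[~sar].mean()
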