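import numpy as np
import pandas as pd
import pytest
from skimage import draw

from nestquant.cells import ClassifiedNuclei
from nestquant.features import (
    ALIASES,
    TumorNest,
    aggregate_patient,
    build_catalog,
    catalog_manifest,
    catalog_names,
    delaunay_area_sum,
    delaunay_edge_stats,
    extract_catalog,
    fractal_dimension,
    nest_boundary,
    object_level_features,
    semantic_level_features,
    with_aliases,
)
from nestquant.nuclei import NucleusObject
from nestquant.synthetic import EPITHELIAL, STROMAL_NONROUND, STROMAL_ROUND


def brute_force_box_counts(pixels, sizes):
    """Independent oracle: scan every grid box and test occupancy."""
    counts = []
    for s in sizes:
        occupied = set()
        for r, c in pixels:
            occupied.add((r // s, c // s))
        counts.append(len(occupied))
    return counts


def sierpinski(depth):
    m = np.ones((1, 1), bool)
    for _ in range(depth):
        z = np.zeros_like(m)
        m = np.block([[m, m], [m, z]])
    return m


class TestCatalog:
    def test_level_counts_400_314_16(self):
        manifest = catalog_manifest()
        counts = manifest["level"].value_counts()
        assert counts["pixel"] == 400
        assert counts["object"] == 314
        assert counts["semantic"] == 16
        assert len(manifest) == 730

    def test_names_unique_and_aliases_resolve(self):
        names = catalog_names()
        assert len(set(names)) == 730
        for target in ALIASES.values():
            assert target in names


class TestFractalDimension:
    def test_line_has_dimension_one(self):
        mask = np.zeros((128, 128), bool)
        mask[64, :] = True
        assert fractal_dimension(mask, [2, 4, 8, 16]) == pytest.approx(1.0, abs=0.1)

    def test_filled_square_has_dimension_two(self):
        mask = np.zeros((128, 128), bool)
        mask[16:112, 16:112] = True
        assert fractal_dimension(mask, [2, 4, 8, 16]) == pytest.approx(2.0, abs=0.1)

    def test_sierpinski_matches_log3_over_log2(self):
        mask = sierpinski(6)
        sizes = [2, 4, 8, 16]
        dim = fractal_dimension(mask, sizes)
        assert dim == pytest.approx(np.log(3) / np.log(2), abs=0.05)

    def test_box_counts_match_bruteforce_oracle(self, rng):
        mask = rng.random((64, 64)) > 0.9
        pixels = np.argwhere(mask)
        sizes = [2, 4, 8, 16]
        from nestquant.features import _box_count

        assert [_box_count(pixels, s) for s in sizes] == brute_force_box_counts(
            [tuple(p) for p in pixels], sizes
        )

    def test_bounded_on_arbitrary_pixel_sets(self, rng):
        for _ in range(5):
            mask = rng.random((64, 64)) > rng.uniform(0.3, 0.99)
            if not mask.any():
                continue
            assert 0.0 <= fractal_dimension(mask) <= 2.0

    def test_empty_boundary_is_missing(self):
        assert np.isnan(fractal_dimension(np.zeros((32, 32), bool)))


class TestDelaunay:
    def test_unit_square_tiling_area(self):
        pts = [(0, 0), (0, 1), (1, 0), (1, 1)]
        assert delaunay_area_sum(pts) == pytest.approx(1.0)

    def test_single_triangle(self):
        assert delaunay_area_sum([(0, 0), (4, 0), (0, 3)]) == pytest.approx(6.0)

    def test_area_sum_equals_convex_hull_area(self, rng):
        from scipy.spatial import ConvexHull

        for _ in range(20):
            pts = rng.uniform(0, 100, (int(rng.integers(5, 100)), 2))
            assert abs(delaunay_area_sum(pts) - ConvexHull(pts).volume) < 1e-6

    def test_degenerate_inputs_are_missing(self):
        assert np.isnan(delaunay_area_sum([(0, 0), (1, 1)]))
        assert np.isnan(delaunay_area_sum([(0, 0), (1, 1), (2, 2), (3, 3)]))
        assert np.isnan(delaunay_edge_stats([(0, 0), (1, 1)])[0])

    def test_edge_stats_on_right_triangle(self):
        mean, var = delaunay_edge_stats([(0, 0), (4, 0), (0, 3)])
        lengths = np.array([4.0, 3.0, 5.0])
        assert mean == pytest.approx(lengths.mean())
        assert var == pytest.approx(lengths.var())


def _nest(i, area, perimeter):
    return TumorNest(
        id=i, centroid=(0.0, 0.0), area=float(area), perimeter=float(perimeter),
        eccentricity=0.5, solidity=0.9, mean_boundary_gradient=10.0,
        major_axis=20.0, minor_axis=10.0, extent=0.7, feret_diameter=22.0,
        orientation=0.3,
    )


def _classified(epi=0, rnd=0, nonrnd=0, area=200.0):
    nuclei = []
    i = 0
    for cls, n in ((EPITHELIAL, epi), (STROMAL_ROUND, rnd), (STROMAL_NONROUND, nonrnd)):
        for _ in range(n):
            i += 1
            obj = NucleusObject(
                id=i, centroid=(float(i), float(i)), area=area, perimeter=50.0,
                eccentricity=0.5, solidity=0.95, mean_boundary_gradient=8.0,
                major_axis=18.0, minor_axis=12.0, extent=0.7,
                feret_diameter=19.0, orientation=0.1, label_class=cls,
            )
            nuclei.append(obj)
    counts = {EPITHELIAL: epi, STROMAL_ROUND: rnd, STROMAL_NONROUND: nonrnd}
    return ClassifiedNuclei(nuclei=nuclei, counts=counts)


class TestObjectLevel:
    def test_two_nest_aggregates_by_hand(self):
        nests = [_nest(1, 100, 40), _nest(2, 300, 80)]
        out = object_level_features(nests, _classified())
        assert out["obj__nest__area__count"] == 2
        assert out["obj__nest__area__mean"] == 200
        assert out["obj__nest__area__variance"] == 10000  # population
        assert out["obj__nest__perimeter__sum"] == 120

    def test_single_nest_zero_variance(self):
        out = object_level_features([_nest(1, 100, 40)], _classified())
        assert out["obj__nest__area__variance"] == 0.0

    def test_aggregates_match_bruteforce_recomputation(self, rng):
        nests = [
            _nest(i, rng.uniform(50, 500), rng.uniform(30, 120)) for i in range(6)
        ]
        out = object_level_features(nests, _classified())
        areas = np.array([n.area for n in nests])
        for agg, fn in (
            ("sum", np.sum), ("mean", np.mean), ("variance", np.var),
            ("min", np.min), ("max", np.max), ("median", np.median),
        ):
            assert out[f"obj__nest__area__{agg}"] == pytest.approx(fn(areas))

    def test_empty_class_gives_missing_aggregates(self):
        out = object_level_features([], _classified(epi=3))
        assert np.isnan(out["obj__nest__area__mean"])
        assert out["obj__nest__area__count"] == 0


class TestSemanticLevel:
    def test_cell_density_hits_printed_middle_category(self):
        # 150 epithelial nuclei in 100000 px^2 of nest -> 0.0015 px^-2,
        # inside the printed middle band 0.0011 - 0.0016
        mask = np.zeros((400, 400), np.uint8)
        mask[:250, :400] = 1  # 100000 px^2
        out = semantic_level_features(mask, _classified(epi=150), [_nest(1, 100000, 1300)])
        assert out["tns_cell_density"] == pytest.approx(0.0015)
        assert 0.0011 < out["tns_cell_density"] < 0.0016

    def test_area_perimeter_ratio(self):
        mask = np.zeros((100, 100), np.uint8)
        mask[:10, :100] = 1  # 1000 px^2 of nest
        out = semantic_level_features(mask, _classified(), [_nest(1, 1000, 100)])
        assert out["tns_area_perimeter_ratio"] == pytest.approx(10.0)

    def test_all_16_match_independent_recomputation(self):
        mask = np.zeros((100, 100), np.uint8)
        mask[:40] = 1
        nuclei = _classified(epi=8, rnd=3, nonrnd=4, area=100.0)
        nests = [_nest(1, 4000, 260)]
        out = semantic_level_features(mask, nuclei, nests)
        assert len(out) == 16
        nest_a, stroma_a, total = 4000.0, 6000.0, 10000.0
        nuclei_a = 15 * 100.0
        expected = {
            "tns_cell_density": 8 / nest_a,
            "stromal_round_cell_density": 3 / stroma_a,
            "stromal_nonround_cell_density": 4 / stroma_a,
            "stromal_cell_density": 7 / stroma_a,
            "tns_nuclei_area_tns_area_ratio": 800 / nest_a,
            "tns_area_perimeter_ratio": nest_a / 260,
            "nest_stroma_area_ratio": nest_a / stroma_a,
            "nest_area_fraction": nest_a / total,
            "stroma_area_fraction": stroma_a / total,
            "nuclei_cytoplasm_ratio": nuclei_a / (total - nuclei_a),
            "nuclei_area_fraction": nuclei_a / total,
            "epithelial_nuclei_fraction": 8 / 15,
            "stromal_round_nuclei_fraction": 3 / 15,
            "stromal_nonround_nuclei_fraction": 4 / 15,
            "mean_epithelial_count_per_nest": 8.0,
            "total_nuclei_density": 15 / total,
        }
        for k, v in expected.items():
            assert out[k] == pytest.approx(v), k

    def test_zero_denominators_are_missing(self):
        mask = np.zeros((50, 50), np.uint8)
        out = semantic_level_features(mask, _classified(), [])
        assert np.isnan(out["tns_cell_density"])
        assert np.isnan(out["tns_area_perimeter_ratio"])
        assert out["nest_stroma_area_ratio"] == 0.0  # zero numerator, not missing


class TestExtractCatalog:
    def test_emits_exactly_730_named_values(self, catalog_vector):
        assert catalog_vector.size == 730
        assert list(catalog_vector.index) == catalog_names()

    def test_pixel_subset_is_400(self, catalog_vector):
        px = [n for n in catalog_vector.index if n.startswith("px__")]
        assert len(px) == 400

    def test_rerun_identical(self, segmented_field, catalog_vector):
        s = segmented_field
        again = extract_catalog(
            s["preprocessed"], s["tissue_mask"], s["nuclei_labels"],
            s["classified"], s["nests"],
        )
        pd.testing.assert_series_equal(catalog_vector, again)

    def test_ratios_within_bounds(self, catalog_vector):
        assert 0 <= catalog_vector["tns_nuclei_area_tns_area_ratio"] <= 1
        assert 0 <= catalog_vector["tns_fractal_dimension"] <= 2
        for name in ("tns_cell_density", "stromal_nonround_cell_density"):
            assert catalog_vector[name] >= 0

    def test_extracted_counts_track_ground_truth(self, segmented_field, catalog_vector):
        """Object counts recovered from segmentation stay within 10% of the
        rendered ground truth."""
        truth = segmented_field["truth"]
        n_total_true = len(truth.nucleus_centroids)
        n_total = sum(
            catalog_vector[f"obj__{c}__area__count"]
            for c in (EPITHELIAL, STROMAL_ROUND, STROMAL_NONROUND)
        )
        assert abs(n_total - n_total_true) / n_total_true <= 0.10
        from skimage import measure

        # reference is the component count of the true mask: nests drawn
        # close together legitimately merge into one connected region
        true_nests = measure.label(truth.nest_mask > 0, connectivity=2).max()
        n_nests = catalog_vector["obj__nest__area__count"]
        assert abs(n_nests - true_nests) <= max(1, 0.10 * true_nests)

    def test_nest_boundary_is_thin_contour(self):
        mask = np.zeros((64, 64), np.uint8)
        rr, cc = draw.disk((32, 32), 20)
        mask[rr, cc] = 1
        b = nest_boundary(mask)
        assert 0 < b.sum() < mask.sum() * 0.25
        assert (b & ~(mask > 0)).sum() == 0


class TestAggregation:
    def test_single_vector_identity(self):
        v = pd.Series({"a": 1.0, "b": 2.0})
        pd.testing.assert_series_equal(aggregate_patient([v]), v)

    def test_mean_over_five_images(self):
        vs = [pd.Series({"a": float(i)}) for i in (1, 2, 3, 4, 5)]
        assert aggregate_patient(vs)["a"] == 3.0

    def test_missing_values_ignored_and_bruteforce_match(self, rng):
        vs = [
            pd.Series({"a": rng.normal(), "b": np.nan if i < 2 else rng.normal()})
            for i in range(5)
        ]
        out = aggregate_patient(vs)
        assert out["a"] == pytest.approx(np.mean([v["a"] for v in vs]))
        assert out["b"] == pytest.approx(np.mean([v["b"] for v in vs[2:]]))
        all_missing = [pd.Series({"c": np.nan}), pd.Series({"c": np.nan})]
        assert np.isnan(aggregate_patient(all_missing)["c"])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient([])

    def test_with_aliases_appends_field_names(self, catalog_vector):
        out = with_aliases(catalog_vector)
        assert out["tns_number"] == catalog_vector["obj__nest__area__count"]
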