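"""Morisita-Horn, quadrat tessellation, nearest-neighbour profiles."""

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, box

from folliscape.compartments import CompartmentGeometry, assign_compartments
from folliscape.panels import PANELS
from folliscape.spatial_stats import (
    colocalization,
    morisita_horn,
    nearest_neighbor_profile,
    quadrat_counts,
    tessellate_compartment,
)
from folliscape.synthetic_data import SceneConfig, generate_cell_map

count_vectors = st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=20)


class TestMorisitaHorn:
    def test_identical_vectors_give_one(self):
        assert morisita_horn([3, 1, 4, 1], [3, 1, 4, 1]) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        assert morisita_horn([5, 0], [0, 7]) == 0.0

    def test_hand_evaluated_instance(self):
        # x=(2,1), y=(1,2): 2*(2+2) / ((5/9 + 5/9)*9) = 8/10
        assert morisita_horn([2, 1], [1, 2]) == pytest.approx(0.8)

    def test_empty_population_is_missing(self):
        assert np.isnan(morisita_horn([0, 0], [1, 2]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            morisita_horn([1, 2], [1, 2, 3])

    @settings(max_examples=100, derandomize=True)
    @given(x=count_vectors, y=count_vectors)
    def test_symmetry_and_range(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        mh_xy = morisita_horn(x, y)
        mh_yx = morisita_horn(y, x)
        if np.isnan(mh_xy):
            assert np.isnan(mh_yx)
        else:
            assert mh_xy == mh_yx
            assert 0.0 <= mh_xy <= 1.0 + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(x=count_vectors, c=st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, x, c):
        if sum(x) == 0:
            return
        y = [v + 1 for v in x]  # any positive partner vector
        assert morisita_horn(np.array(x) * c, y) == pytest.approx(morisita_horn(x, y), abs=1e-12)


class TestTessellation:
    def test_rectangle_three_quadrats(self):
        geom = CompartmentGeometry(box(0, 0, 300, 100), [])
        tess = tessellate_compartment(geom, "inter", seed_spacing=100.0)
        assert len(tess.seeds) == 3
        np.testing.assert_allclose(tess.areas_um2, 10000.0)

    def test_area_conservation_random_geometries(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            folls = [Point(rng.uniform(150, 450), rng.uniform(150, 450)).buffer(rng.uniform(60, 110))]
            geom = CompartmentGeometry(box(0, 0, 600, 600), folls)
            for compartment in ("intra", "inter"):
                tess = tessellate_compartment(geom, compartment, seed_spacing=60.0)
                target = geom.areas_um2[compartment]
                assert abs(tess.areas_um2.sum() - target) / target < 0.005

    def test_every_cell_in_exactly_one_quadrat(self):
        rng = np.random.default_rng(1)
        geom = CompartmentGeometry(box(0, 0, 500, 500),
                                   [Point(250, 250).buffer(120)])
        tess = tessellate_compartment(geom, "inter", seed_spacing=50.0)
        pts = rng.uniform(0, 500, (1000, 2))
        keep = ~shapely.contains_xy(Point(250, 250).buffer(120), pts[:, 0], pts[:, 1])
        pts = pts[keep]
        counts = quadrat_counts(tess, pts)
        assert counts.sum() == len(pts)
        # cross-check against shapely point-in-polygon on the clipped cells
        poly_counts = np.zeros(len(tess.polygons), dtype=int)
        for x, y in pts:
            hits = [i for i, p in enumerate(tess.polygons)
                    if shapely.intersects_xy(p, x, y)]
            assert len(hits) >= 1
            poly_counts[hits[0]] += 1
        np.testing.assert_array_equal(np.sort(counts), np.sort(poly_counts))

    def test_tiny_compartment_single_quadrat_with_warning(self):
        geom = CompartmentGeometry(box(0, 0, 20, 20), [])
        with pytest.warns(UserWarning, match="single-quadrat"):
            tess = tessellate_compartment(geom, "inter", seed_spacing=100.0)
        assert len(tess.seeds) == 1

    def test_zero_area_compartment_rejected(self):
        geom = CompartmentGeometry(box(0, 0, 100, 100), [])
        with pytest.raises(ValueError, match="zero area"):
            tessellate_compartment(geom, "intra", seed_spacing=50.0)


def _cell_map(coords_by_label, tile_id="t0"):
    from folliscape.panels import parse_label

    markers = PANELS["t_cell"]
    frames = []
    for label, pts in coords_by_label.items():
        want = parse_label(label)
        df = pd.DataFrame(np.asarray(pts, dtype=float).reshape(-1, 2), columns=["x_um", "y_um"])
        for m in markers:
            df[f"{m}_pos"] = bool(want.get(m, False))
        df["phenotype"] = label
        frames.append(df)
    cm = pd.concat(frames, ignore_index=True)
    cm.insert(0, "cell_id", [f"c{i}" for i in range(len(cm))])
    cm.insert(1, "tile_id", tile_id)
    cm["patient_id"] = "P0"
    cm["compartment"] = "inter"
    return cm


class TestColocalization:
    def test_identical_patterns_give_one(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 300, (80, 2))
        cm = _cell_map({"CD8+FOXP3+": pts, "CD4+CD8+": pts.copy()})
        geom = CompartmentGeometry(box(0, 0, 300, 300), [], tile_id="t0")
        tess = {"t0": tessellate_compartment(geom, "inter", 50.0, build_polygons=False)}
        res = colocalization(cm, "CD8+FOXP3+", "CD4+CD8+", tess, "inter")
        assert res[0].mh == pytest.approx(1.0)

    def test_segregated_halves_approach_zero(self):
        rng = np.random.default_rng(3)
        a = np.column_stack([rng.uniform(0, 140, 200), rng.uniform(0, 300, 200)])
        b = np.column_stack([rng.uniform(160, 300, 200), rng.uniform(0, 300, 200)])
        cm = _cell_map({"CD8+FOXP3+": a, "CD4+CD8+": b})
        geom = CompartmentGeometry(box(0, 0, 300, 300), [], tile_id="t0")
        tess = {"t0": tessellate_compartment(geom, "inter", 30.0, build_polygons=False)}
        res = colocalization(cm, "CD8+FOXP3+", "CD4+CD8+", tess, "inter")
        assert res[0].mh < 0.05

    def test_absent_phenotype_flagged_missing(self):
        rng = np.random.default_rng(4)
        cm = _cell_map({"CD8+FOXP3+": rng.uniform(0, 300, (30, 2))})
        geom = CompartmentGeometry(box(0, 0, 300, 300), [], tile_id="t0")
        tess = {"t0": tessellate_compartment(geom, "inter", 50.0, build_polygons=False)}
        res = colocalization(cm, "CD8+FOXP3+", "CD4+CD8+", tess, "inter")
        assert np.isnan(res[0].mh)
        assert res[0].reason is not None

    def test_mh_increases_with_coupling_strength(self):
        # Thomas-style coupling: mean MH strictly increasing over kappa
        means = []
        for kappa in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(20):
                cfg = SceneConfig(width_um=400, height_um=400, n_follicles=0,
                                  phenotype_densities={"CD8+FOXP3+": (0, 1.0), "CD4+CD8+": (0, 1.0)},
                                  coupling={("CD8+FOXP3+", "CD4+CD8+"): (kappa, 5.0)} if kappa > 0 else {},
                                  seed=seed)
                truth = generate_cell_map(cfg)
                geom = CompartmentGeometry(truth.tile_polygon, [], truth.tile_id)
                cells = truth.cells.copy()
                cells["patient_id"] = "P0"
                cells = assign_compartments(cells, geom)
                tess = {truth.tile_id: tessellate_compartment(geom, "inter", 25.0, build_polygons=False)}
                r = colocalization(cells, "CD8+FOXP3+", "CD4+CD8+", tess, "inter")[0]
                vals.append(r.mh)
            means.append(np.nanmean(vals))
        assert means[0] < means[1] < means[2]

    def test_csr_baseline_band_and_quadrat_size_effect(self):
        # two independent phenotypes at equal intensity: MH well above 0,
        # increasing with quadrat size (documented small-count behaviour)
        mh_small, mh_large = [], []
        geom = CompartmentGeometry(box(0, 0, 400, 400), [], tile_id="t0")
        tess_s = {"t0": tessellate_compartment(geom, "inter", 50.0, build_polygons=False)}
        tess_l = {"t0": tessellate_compartment(geom, "inter", 100.0, build_polygons=False)}
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cm = _cell_map({"CD8+FOXP3+": rng.uniform(0, 400, (240, 2)),
                            "CD4+CD8+": rng.uniform(0, 400, (240, 2))})
            mh_small.append(colocalization(cm, "CD8+FOXP3+", "CD4+CD8+", tess_s, "inter")[0].mh)
            mh_large.append(colocalization(cm, "CD8+FOXP3+", "CD4+CD8+", tess_l, "inter")[0].mh)
        assert 0.6 < np.mean(mh_small) < 1.0
        assert np.mean(mh_large) > np.mean(mh_small)


class TestNearestNeighbor:
    def test_simple_instance(self):
        cm = _cell_map({"CD8+FOXP3+": [(0.0, 0.0)],
                        "CD4+CD8+": [(3.0, 0.0)],
                        "CD4+FOXP3+": [(4.0, 0.0)]})
        res = nearest_neighbor_profile(cm, "CD8+FOXP3+", ["CD4+CD8+", "CD4+FOXP3+"], "inter")
        assert res.per_cell["nn_phenotype"].iloc[0] == "CD4+CD8+"
        assert res.per_cell["nn_distance_um"].iloc[0] == pytest.approx(3.0)

    def test_self_excluded_when_reference_in_candidates(self):
        cm = _cell_map({"CD8+FOXP3+": [(0.0, 0.0), (10.0, 0.0)]})
        res = nearest_neighbor_profile(cm, "CD8+FOXP3+", ["CD8+FOXP3+"], "inter")
        assert (res.per_cell["nn_distance_um"] > 0).all()
        np.testing.assert_allclose(res.per_cell["nn_distance_um"], 10.0)

    def test_no_candidates_returns_none(self):
        cm = _cell_map({"CD8+FOXP3+": [(0.0, 0.0)]})
        assert nearest_neighbor_profile(cm, "CD8+FOXP3+", ["CD4+CD8+"], "inter") is None

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(11)
        ref = rng.uniform(0, 400, (120, 2))
        cand = rng.uniform(0, 400, (380, 2))
        cm = _cell_map({"CD8+FOXP3+": ref, "CD4+CD8+": cand})
        res = nearest_neighbor_profile(cm, "CD8+FOXP3+", ["CD4+CD8+"], "inter")
        got = res.per_cell.sort_values("cell_id")["nn_distance_um"].to_numpy()
        # brute force O(n^2)
        from scipy.spatial.distance import cdist
        expected = cdist(ref, cand).min(axis=1)
        np.testing.assert_allclose(np.sort(got), np.sort(expected))

    def test_translation_rotation_invariance(self):
        rng = np.random.default_rng(13)
        ref = rng.uniform(0, 200, (40, 2))
        cand = rng.uniform(0, 200, (60, 2))
        base = nearest_neighbor_profile(_cell_map({"CD8+FOXP3+": ref, "CD4+CD8+": cand}),
                                        "CD8+FOXP3+", ["CD4+CD8+"], "inter")
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([37.0, -12.0])
        moved = nearest_neighbor_profile(
            _cell_map({"CD8+FOXP3+": ref @ rot.T + shift, "CD4+CD8+": cand @ rot.T + shift}),
            "CD8+FOXP3+", ["CD4+CD8+"], "inter")
        np.testing.assert_allclose(
            np.sort(base.per_cell["nn_distance_um"]),
            np.sort(moved.per_cell["nn_distance_um"]), rtol=1e-9)
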