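"""Spatial annotation: home flags, tract components, POI/hub nesting,
linear features, hub coverage."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, box

from exposeg.annotation import (annotate_edges, annotate_home, annotate_linear,
                                annotate_poi, annotate_hub, classify_component,
                                hub_coverage_stats, load_layer, locate_points)
from exposeg.geometry import LocalProjection

M_LAT = 1.0 / 111_320.0
PROJ = LocalProjection(38.0, -95.0)


def sq(cx_m, cy_m, side_m):
    """Square polygon in lon/lat centred at local-metre coordinates."""
    half = side_m / 2.0
    return PROJ.unproject_geometry(box(cx_m - half, cy_m - half,
                                       cx_m + half, cy_m + half))


def feat(fid, kind, geom, **props):
    return {"id": fid, "kind": kind, "geometry": geom, "props": props}


def edge_at(x_m, y_m, i="a", j="b", t=0):
    lat, lon = PROJ.to_latlon(x_m, y_m)
    return {"user_i": i, "user_j": j, "k": 1, "t": t,
            "lat": float(lat), "lon": float(lon)}


def ind_at(entries):
    rows = []
    for uid, (x_m, y_m, tract) in entries.items():
        lat, lon = PROJ.to_latlon(x_m, y_m)
        rows.append((uid, float(lat), float(lon), tract))
    return pd.DataFrame(rows, columns=["user_id", "home_lat", "home_lon",
                                       "home_tract_id"]).set_index("user_id")


@pytest.fixture(scope="module")
def tract_layer():
    return load_layer([feat("A", "tract", sq(500, 500, 1000)),
                       feat("B", "tract", sq(1500, 500, 1000)),
                       feat("C", "tract", sq(500, 1500, 1000))], "tract")


class TestLocatePoints:
    def test_containment_and_outside(self, tract_layer):
        lat, lon = PROJ.to_latlon(np.array([200.0, 1700.0, 5000.0]),
                                  np.array([200.0, 300.0, 5000.0]))
        assert locate_points(lat, lon, tract_layer).tolist() == ["A", "B", ""]

    def test_boundary_point_counts_as_inside(self, tract_layer):
        lat, lon = PROJ.to_latlon(0.0, 500.0)  # on A's west edge
        assert locate_points([lat], [lon], tract_layer)[0] == "A"

    def test_smallest_area_wins_on_overlap(self):
        layer = load_layer([feat("big", "poi", sq(0, 0, 500)),
                            feat("small", "poi", sq(0, 0, 60))], "poi")
        lat, lon = PROJ.to_latlon(10.0, 0.0)
        assert locate_points([lat], [lon], layer)[0] == "small"

    def test_matches_bruteforce_point_in_polygon(self, tract_layer):
        rng = np.random.default_rng(2)
        xs = rng.uniform(-500, 2500, 200)
        ys = rng.uniform(-500, 2500, 200)
        lat, lon = PROJ.to_latlon(xs, ys)
        got = locate_points(lat, lon, tract_layer)
        for i in range(200):
            pt = Point(lon[i], lat[i])
            covering = [(g.area, fid) for fid, g in
                        zip(tract_layer.ids, tract_layer.geoms) if g.covers(pt)]
            expect = min(covering)[1] if covering else ""
            assert got[i] == expect

    def test_invalid_polygon_rejected_at_load(self):
        from shapely.geometry import Polygon
        bad = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])  # self-intersecting
        with pytest.raises(ValueError, match="oops"):
            load_layer([feat("oops", "poi", bad)], "poi")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            load_layer([feat("x", "poi", sq(0, 0, 10)),
                        feat("x", "poi", sq(50, 0, 10))], "poi")


class TestAnnotateHome:
    def test_exposure_at_own_home_flagged(self):
        ind = ind_at({"a": (100.0, 100.0, "A"), "b": (900.0, 900.0, "A")})
        edges = pd.DataFrame([edge_at(100.0, 100.0)])
        out = annotate_home(edges, ind)
        assert bool(out["at_home_i"].iloc[0]) is True
        assert bool(out["at_home_j"].iloc[0]) is False

    def test_sixty_metres_from_both_homes_unflagged(self):
        ind = ind_at({"a": (0.0, 0.0, "A"), "b": (120.0, 0.0, "A")})
        out = annotate_home(pd.DataFrame([edge_at(60.0, 0.0)]), ind)
        assert not out["at_home_i"].iloc[0] and not out["at_home_j"].iloc[0]

    def test_flags_match_bruteforce_distance(self):
        from exposeg.geometry import haversine_m
        rng = np.random.default_rng(7)
        ind = ind_at({f"u{k}": (rng.uniform(0, 500), rng.uniform(0, 500), "A")
                      for k in range(12)})
        edges = pd.DataFrame([edge_at(rng.uniform(0, 500), rng.uniform(0, 500),
                                      i=f"u{rng.integers(0, 12)}",
                                      j=f"u{rng.integers(0, 12)}")
                              for _ in range(60)])
        out = annotate_home(edges, ind)
        for _, e in out.iterrows():
            for side in ("i", "j"):
                h = ind.loc[e[f"user_{side}"]]
                d = haversine_m(e["lat"], e["lon"], h.home_lat, h.home_lon)
                assert e[f"at_home_{side}"] == (d <= 50.0)

    def test_missing_home_leaves_flag_unset(self):
        ind = ind_at({"a": (0.0, 0.0, "A")})
        ind.loc["b"] = (np.nan, np.nan, "A")
        out = annotate_home(pd.DataFrame([edge_at(0.0, 0.0)]), ind)
        assert not out["at_home_j"].iloc[0]


class TestComponent:
    def test_three_way_scheme(self, tract_layer):
        ind = ind_at({"a": (100, 100, "A"), "b": (200, 200, "A"),
                      "c": (1500, 500, "B"), "d": (500, 1500, "C")})
        edges = pd.DataFrame([
            edge_at(300, 300, "a", "b"),    # both in home tract A
            edge_at(400, 400, "a", "c"),    # only a at home (c's tract is B)
            edge_at(1800, 800, "a", "d"),   # neither (exposure in B)
        ])
        out = classify_component(edges, ind, tract_layer)
        assert out["component"].tolist() == [
            "both_in_home_tract", "one_in_home_tract", "neither_in_home_tract"]

    def test_out_of_region_is_neither(self, tract_layer):
        ind = ind_at({"a": (100, 100, "A"), "b": (200, 200, "A")})
        out = classify_component(pd.DataFrame([edge_at(9000, 9000)]),
                                 ind, tract_layer)
        assert out["component"].iloc[0] == "neither_in_home_tract"

    def test_component_shares_sum_to_one(self, tract_layer):
        rng = np.random.default_rng(3)
        ind = ind_at({f"u{k}": (rng.uniform(0, 2000), rng.uniform(0, 1000),
                                rng.choice(["A", "B"]))
                      for k in range(10)})
        edges = pd.DataFrame([edge_at(rng.uniform(0, 2000),
                                      rng.uniform(0, 1000),
                                      f"u{rng.integers(0, 10)}",
                                      f"u{rng.integers(0, 10)}")
                              for _ in range(50)])
        out = classify_component(edges, ind, tract_layer)
        shares = out["component"].value_counts(normalize=True)
        assert shares.sum() == pytest.approx(1.0)


class TestPoiHubLinear:
    def test_poi_and_nested_hub_both_set(self):
        poi_layer = load_layer([feat("rest", "poi", sq(100, 100, 40),
                                     naics="722511")], "poi")
        hub_layer = load_layer([feat("mall", "hub", sq(100, 100, 300))], "hub")
        edges = pd.DataFrame([edge_at(100, 100), edge_at(220, 100),
                              edge_at(900, 900)])
        out = annotate_hub(annotate_poi(edges, poi_layer), hub_layer)
        assert out["poi_id"].tolist() == ["rest", "", ""]
        assert out["poi_category"].tolist() == ["722511", "", ""]
        assert out["hub_id"].tolist() == ["mall", "mall", ""]

    def test_linear_buffer_rule(self):
        road = PROJ.unproject_geometry(LineString([(0, 0), (1000, 0)]))
        layer = load_layer([feat("r1", "road", road)], "road")
        edges = pd.DataFrame([edge_at(500, 0), edge_at(500, 19),
                              edge_at(500, 25)])
        out = annotate_linear(edges, layer)
        assert out["near_road"].tolist() == [True, True, False]

    def test_linear_matches_bruteforce_segment_distance(self):
        rng = np.random.default_rng(11)
        pts_m = [(rng.uniform(0, 300), rng.uniform(0, 300)) for _ in range(6)]
        road = PROJ.unproject_geometry(LineString(pts_m))
        layer = load_layer([feat("r", "road", road)], "road")
        edges = pd.DataFrame([edge_at(rng.uniform(0, 300), rng.uniform(0, 300))
                              for _ in range(80)])
        out = annotate_linear(edges, layer)
        from shapely.geometry import LineString as LS
        seg = LS(pts_m)
        x, y = PROJ.to_xy(edges["lat"].to_numpy(), edges["lon"].to_numpy())
        for flag, xi, yi in zip(out["near_road"], x, y):
            assert flag == (seg.distance(Point(xi, yi)) <= 20.0 + 1e-9)


class TestHubCoverage:
    def test_no_hubs_gives_zero_fractions(self):
        layer = load_layer([], "hub")
        edges = pd.DataFrame([edge_at(0, 0)])
        assert hub_coverage_stats(edges, layer, sq(0, 0, 1000)) == (0.0, 0.0)

    def test_full_buffer_coverage_gives_land_fraction_one(self):
        layer = load_layer([feat("h", "hub", sq(500, 500, 200))], "hub")
        region = sq(500, 500, 1000)
        frac_exp, frac_land = hub_coverage_stats(
            pd.DataFrame([edge_at(500, 500)]), layer, region, radius_m=2000)
        assert frac_land == pytest.approx(1.0, abs=1e-9)
        assert frac_exp == 1.0

    def test_exposure_share_versus_land_share(self):
        """Exposures concentrated at the hub exceed the land share."""
        layer = load_layer([feat("h", "hub", sq(500, 500, 100))], "hub")
        region = sq(2500, 2500, 5000)
        edges = pd.DataFrame([edge_at(500 + dx, 500) for dx in range(0, 90, 10)]
                             + [edge_at(4000, 4000)])
        frac_exp, frac_land = hub_coverage_stats(edges, layer, region,
                                                 radius_m=1000)
        assert frac_exp == pytest.approx(9 / 10)
        assert frac_land < 0.2
        assert frac_exp > frac_land


def test_annotations_idempotent_and_order_invariant(tract_layer):
    ind = ind_at({"a": (100, 100, "A"), "b": (1500, 400, "B")})
    poi_layer = load_layer([feat("p", "poi", sq(100, 100, 40), naics="1")], "poi")
    hub_layer = load_layer([feat("h", "hub", sq(100, 100, 300))], "hub")
    edges = pd.DataFrame([edge_at(100, 100), edge_at(1500, 400),
                          edge_at(700, 900)])
    once = annotate_edges(edges, ind, tract_layer, poi_layer, hub_layer)
    twice = annotate_edges(once, ind, tract_layer, poi_layer, hub_layer)
    pd.testing.assert_frame_equal(once, twice)
    flipped = annotate_edges(edges.iloc[::-1].reset_index(drop=True), ind,
                             tract_layer, poi_layer, hub_layer)
    pd.testing.assert_frame_equal(
        flipped.sort_values("lat").reset_index(drop=True),
        once.sort_values("lat").reset_index(drop=True))
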