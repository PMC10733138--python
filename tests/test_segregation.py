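"""Ego records, naive/corrected estimators, NSI, decompositions."""

import numpy as np
import pandas as pd
import pytest

from exposeg import CityConfig, generate_city
from exposeg.mixed_model import MixedModelFit
from exposeg.segregation import (build_ego_records,
                                 corrected_exposure_segregation, decompose,
                                 estimate_exposure_segregation,
                                 fit_mixed_model, naive_exposure_segregation,
                                 neighbourhood_sorting_index,
                                 synthetic_tract_network)


def edges_of(pairs, **extra_cols):
    df = pd.DataFrame(pairs, columns=["user_i", "user_j"])
    df["k"] = 1
    df["t"] = extra_cols.pop("t", 0)
    df["lat"] = np.nan
    df["lon"] = np.nan
    for c, v in extra_cols.items():
        df[c] = v
    return df


def individuals_of(ses: dict) -> pd.DataFrame:
    return pd.DataFrame({"ses": pd.Series(ses, dtype=float)}).rename_axis("user_id")


class TestBuildEgoRecords:
    def test_partner_deduplication_and_no_self(self):
        ind = individuals_of({"a": 1000, "b": 2000, "c": 3000, "d": 4000})
        e = edges_of([("a", "b")] * 5 + [("a", "c"), ("a", "d"), ("b", "c")])
        rec = build_ego_records(e, ind)
        by_ego = dict(zip(rec.ego_ids, rec.sizes))
        assert by_ego["a"] == 3          # b deduplicated to one partner
        assert by_ego["b"] == 2          # a and c
        assert "a" not in []             # ego never own partner by construction
        starts = np.r_[0, np.cumsum(rec.sizes)[:-1]]
        a_pos = list(rec.ego_ids).index("a")
        a_partners = rec.y[starts[a_pos]:starts[a_pos] + rec.sizes[a_pos]]
        assert sorted(a_partners) == [2000.0, 3000.0, 4000.0]

    def test_resident_without_exposures_has_no_record(self):
        ind = individuals_of({"a": 1000, "b": 2000, "c": 3000})
        rec = build_ego_records(edges_of([("a", "b")]), ind)
        assert "c" not in rec.ego_ids

    def test_region_restricts_egos_not_partners(self):
        ind = individuals_of({"a": 1000, "b": 2000, "out": 9000})
        rec = build_ego_records(edges_of([("a", "out"), ("b", "out")]), ind,
                                region_egos=["a", "b"])
        assert set(rec.ego_ids) == {"a", "b"}
        assert set(rec.y) == {9000.0}

    def test_x_standardized_in_region(self):
        ind = individuals_of({f"u{i}": 1000.0 + 100 * i for i in range(10)})
        e = edges_of([(f"u{i}", f"u{(i + 1) % 10}") for i in range(10)])
        rec = build_ego_records(e, ind)
        assert rec.x.mean() == pytest.approx(0.0, abs=1e-12)
        assert rec.x.std() == pytest.approx(1.0, abs=1e-12)

    def test_too_few_egos_refused(self):
        ind = individuals_of({"a": 1000, "b": 2000})
        with pytest.raises(ValueError, match="fewer than 2 egos"):
            build_ego_records(edges_of([("a", "b")]), ind, region_egos=["a"])


class TestNaive:
    def test_partner_mean_equal_to_own_ses_gives_one(self):
        ind = individuals_of({f"u{i}": 1000.0 * (i + 1) for i in range(6)})
        # pair each ego with a same-SES twin
        ind2 = pd.concat([ind, ind.rename(index=lambda u: u + "t")])
        e = edges_of([(f"u{i}", f"u{i}t") for i in range(6)])
        rec = build_ego_records(e, ind2)
        assert naive_exposure_segregation(rec).value == pytest.approx(1.0)

    def test_constant_partner_means_undefined(self):
        ind = individuals_of({"a": 1000, "b": 2000, "z": 5000})
        rec = build_ego_records(edges_of([("a", "z"), ("b", "z")]), ind,
                                region_egos=["a", "b"])
        est = naive_exposure_segregation(rec)
        assert not est.estimable and "zero variance" in est.note

    def test_ten_ego_fixture_matches_pearson_formula(self):
        rng = np.random.default_rng(5)
        ses = {f"u{i}": float(rng.uniform(800, 5000)) for i in range(10)}
        ind = individuals_of(ses)
        pairs = [(f"u{i}", f"u{j}") for i in range(10) for j in range(10)
                 if i < j and rng.random() < 0.5]
        rec = build_ego_records(edges_of(pairs), ind)
        got = naive_exposure_segregation(rec).value
        # direct formula on hand-assembled partner means
        partners = {u: set() for u in ses}
        for i, j in pairs:
            partners[i].add(j)
            partners[j].add(i)
        egos = [u for u in sorted(ses) if partners[u]]
        x = np.array([ses[u] for u in egos])
        ym = np.array([np.mean([ses[p] for p in partners[u]]) for u in egos])
        expect = (((x - x.mean()) * (ym - ym.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((ym - ym.mean()) ** 2).sum()))
        assert got == pytest.approx(expect, abs=1e-12)


class TestCorrected:
    @pytest.mark.parametrize("a,var1,expect", [
        (1.0, 0.0, 1.0),
        (0.0, 0.5, 0.0),
        (3.0, 16.0, 0.6),
        (-3.0, 16.0, -0.6),
    ])
    def test_formula_values(self, a, var1, expect):
        fit = MixedModelFit(a=a, b=0.0, var1=var1, var2=1.0, converged=True,
                            n_egos=100, n_obs=500)
        assert corrected_exposure_segregation(fit).value == \
            pytest.approx(expect, abs=1e-12)

    def test_double_degenerate_returns_zero_with_note(self):
        fit = MixedModelFit(0.0, 1.0, 0.0, 1.0, True, 10, 50)
        est = corrected_exposure_segregation(fit)
        assert est.value == 0.0 and "degenerate" in est.note

    def test_nonconverged_value_withheld(self):
        fit = MixedModelFit(np.nan, np.nan, np.nan, np.nan, False, 10, 50)
        est = corrected_exposure_segregation(fit)
        assert not est.estimable and "converge" in est.note

    def test_scale_invariance_of_corrected_estimate(self):
        """Affine rescaling of SES leaves the corrected estimate unchanged."""
        rng = np.random.default_rng(3)
        ses = {f"u{i}": float(rng.uniform(800, 5000)) for i in range(40)}
        pairs = [(f"u{i}", f"u{rng.integers(0, 40)}") for i in range(40)
                 for _ in range(3)]
        pairs = [(a, b) for a, b in pairs if a != b]
        base = estimate_exposure_segregation(
            build_ego_records(edges_of(pairs), individuals_of(ses)), "mixed")
        scaled = {u: 3.0 * v + 500.0 for u, v in ses.items()}
        alt = estimate_exposure_segregation(
            build_ego_records(edges_of(pairs), individuals_of(scaled)), "mixed")
        assert alt.value == pytest.approx(base.value, abs=1e-6)

    def test_estimates_bounded_by_one(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            ses = {f"u{i}": float(rng.uniform(500, 8000)) for i in range(30)}
            pairs = [(f"u{i}", f"u{(i + k) % 30}")
                     for i in range(30) for k in (1, 2)]
            rec = build_ego_records(edges_of(pairs), individuals_of(ses))
            for method in ("naive", "mixed"):
                v = estimate_exposure_segregation(rec, method).value
                assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9


class TestNSI:
    def _ind(self, ses_by_tract):
        rows = []
        for tract, vals in ses_by_tract.items():
            for i, s in enumerate(vals):
                rows.append((f"{tract}{i}", float(s), tract))
        return pd.DataFrame(rows, columns=["user_id", "ses", "home_tract_id"]
                            ).set_index("user_id")

    def test_perfect_sorting(self):
        nsi = neighbourhood_sorting_index(self._ind({"A": [1, 1], "B": [5, 5]}))
        assert nsi.value == pytest.approx(1.0)

    def test_three_tract_fixture_matches_hand_computation(self):
        ind = self._ind({"A": [1, 2], "B": [4, 6], "C": [9, 10, 11]})
        x = ind["ses"].to_numpy()
        means = {"A": 1.5, "B": 5.0, "C": 10.0}
        m = ind["home_tract_id"].map(means).to_numpy()
        expect = np.corrcoef(x, m)[0, 1]
        assert neighbourhood_sorting_index(ind).value == \
            pytest.approx(expect, abs=1e-12)

    def test_random_assignment_near_zero(self):
        rng = np.random.default_rng(1)
        ind = pd.DataFrame({
            "ses": rng.lognormal(7, 0.5, 3000),
            "home_tract_id": rng.choice([f"t{k}" for k in range(20)], 3000),
        }, index=[f"u{i}" for i in range(3000)])
        assert abs(neighbourhood_sorting_index(ind).value) < 0.12

    def test_single_tract_undefined(self):
        est = neighbourhood_sorting_index(self._ind({"A": [1, 2, 3]}))
        assert not est.estimable and "tract" in est.note


@pytest.fixture(scope="module")
def city_individuals():
    cfg = CityConfig(n_individuals=1200, n_tracts=12, n_pois=10, n_hubs=2,
                     n_days=2, seed=5)
    return generate_city(cfg).individuals.rename(
        columns={"tract_id": "home_tract_id"})


class TestSyntheticTractNetwork:

    def test_dense_network_reproduces_nsi(self, city_individuals):
        """Exposures uniform within tract (all co-residents) make exposure
        segregation the neighbourhood sorting index, up to the
        ego-inclusion convention (< 0.01 at these tract sizes)."""
        nsi = neighbourhood_sorting_index(city_individuals)
        edges = synthetic_tract_network(city_individuals, None, seed=0)
        rec = build_ego_records(edges, city_individuals)
        mixed = estimate_exposure_segregation(rec, "mixed")
        assert mixed.value == pytest.approx(nsi.value, abs=0.01)

    def test_fixed_seed_reproducible(self, city_individuals):
        a = synthetic_tract_network(city_individuals, 3, seed=7)
        b = synthetic_tract_network(city_individuals, 3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_sparse_draws_recover_nsi_with_mixed_model(self, city_individuals):
        """3 partners per ego: the mixed model removes the attenuation and
        the replicate-mean matches the dense-network NSI."""
        nsi = neighbourhood_sorting_index(city_individuals).value
        vals = []
        for s in range(8):
            edges = synthetic_tract_network(city_individuals, 3, seed=s)
            rec = build_ego_records(edges, city_individuals)
            vals.append(estimate_exposure_segregation(rec, "mixed").value)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - nsi) < max(3 * se, 0.02)
        naive = [estimate_exposure_segregation(
            build_ego_records(synthetic_tract_network(city_individuals, 3,
                                                      seed=s),
                              city_individuals), "naive").value
                 for s in range(4)]
        assert np.mean(naive) < nsi - 0.02  # the attenuation being corrected


class TestDecompose:
    def _setup(self):
        rng = np.random.default_rng(4)
        ses = {f"u{i}": float(rng.uniform(800, 6000)) for i in range(30)}
        ind = individuals_of(ses)
        pairs = [(f"u{i}", f"u{(i + k) % 30}") for i in range(30)
                 for k in (1, 2, 3)]
        e = edges_of(pairs)
        e["component"] = np.where(np.arange(len(e)) % 3 == 0,
                                  "both_in_home_tract",
                                  "neither_in_home_tract")
        e["poi_category"] = np.where(np.arange(len(e)) % 2 == 0, "722511", "")
        e["hub_id"] = ""
        return e, ind

    def test_single_category_stratum_equals_global(self):
        e, ind = self._setup()
        e["poi_category"] = "722511"
        global_est = estimate_exposure_segregation(
            build_ego_records(e, ind), "mixed")
        strata = decompose(e, ind, "poi_category")
        assert len(strata) == 1
        assert strata[0].value == pytest.approx(global_est.value, abs=1e-9)

    def test_time_windows_partition_obs_counts(self):
        e, ind = self._setup()
        e["t"] = np.arange(len(e)) * 3000  # spread over the day
        strata = decompose(e, ind, "time_window")
        rec_total = build_ego_records(e, ind)
        assert sum(s.n_obs for s in strata if np.isfinite(s.n_obs)) \
            == rec_total.n_obs

    def test_empty_stratum_marked_not_estimable(self):
        e, ind = self._setup()
        e.loc[e["component"] == "both_in_home_tract", "component"] = \
            "neither_in_home_tract"
        e2 = e.iloc[:1].copy()
        e2["component"] = "both_in_home_tract"
        strata = decompose(pd.concat([e, e2]), ind, "component")
        both = [s for s in strata if s.stratum == "both_in_home_tract"][0]
        assert not both.estimable and "not estimable" in both.note

    def test_hub_stratifier_splits_in_and_out(self):
        e, ind = self._setup()
        e.loc[: len(e) // 2, "hub_id"] = "h0"
        strata = {s.stratum for s in decompose(e, ind, "hub", method="naive")}
        assert strata == {"hub", "non_hub"}

    def test_in_tract_homophily_raises_both_stratum(self):
        """Designed contrast: within-tract partners SES-similar, cross-tract
        partners random — the both_in_home_tract stratum is more segregated."""
        rng = np.random.default_rng(9)
        rows = {}
        for tract in range(6):
            level = 1000.0 * (tract + 1)
            for i in range(10):
                rows[f"t{tract}_{i}"] = level * rng.uniform(0.95, 1.05)
        ind = individuals_of(rows)
        ids = list(rows)
        pairs, comps = [], []
        for tract in range(6):                       # within-tract edges
            members = [u for u in ids if u.startswith(f"t{tract}_")]
            for a in range(len(members) - 1):
                pairs.append((members[a], members[a + 1]))
                comps.append("both_in_home_tract")
        for _ in range(120):                         # random cross edges
            a, b = rng.choice(ids, 2, replace=False)
            pairs.append((a, b))
            comps.append("neither_in_home_tract")
        e = edges_of(pairs)
        e["component"] = comps
        strata = {s.stratum: s.value
                  for s in decompose(e, ind, "component", method="naive")}
        assert strata["both_in_home_tract"] > strata["neither_in_home_tract"]


def test_bootstrap_ci_brackets_estimate():
    from exposeg.inference import BootstrapSpec
    rng = np.random.default_rng(2)
    ses = {f"u{i}": float(rng.uniform(800, 6000)) for i in range(60)}
    pairs = [(f"u{i}", f"u{(i + k) % 60}") for i in range(60) for k in (1, 2)]
    rec = build_ego_records(edges_of(pairs), individuals_of(ses))
    est = estimate_exposure_segregation(
        rec, "naive", bootstrap_spec=BootstrapSpec(n_reps=200, seed=3))
    assert est.ci_low <= est.value <= est.ci_high
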