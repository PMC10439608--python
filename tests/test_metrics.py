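import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from magcurate import (
    ColumnSpec,
    FeatureGroup,
    MetricError,
    QualityTier,
    adjusted_rand,
    build_table,
    classify_quality,
    compare_bins,
    completeness_redundancy,
    set_flag,
    silhouette_scores,
)
from oracles import brute_ari, brute_silhouette


def _random_instance(rng, n_max=60, d_max=4, k_max=5):
    n = int(rng.integers(6, n_max))
    d = int(rng.integers(1, d_max + 1))
    k = int(rng.integers(2, k_max + 1))
    pts = rng.normal(size=(n, d))
    labels = rng.integers(0, k, size=n)
    while len(set(labels)) < 2:
        labels = rng.integers(0, k, size=n)
    coords = {f"c{i}": tuple(pts[i]) for i in range(n)}
    assignment = {f"c{i}": f"bin{labels[i]}" for i in range(n)}
    return coords, assignment, pts, labels


class TestSilhouette:
    def test_worked_four_point_example(self):
        coords = {"a1": (0, 0), "a2": (0, 1), "b1": (10, 0), "b2": (10, 1)}
        labels = {k: k[0] for k in coords}
        res = silhouette_scores(coords, labels, standardize=False)
        assert res.overall_mean == pytest.approx(0.900, abs=5e-4)
        assert res.n_used == 4
        assert set(res.per_bin_mean) == {"a", "b"}

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            coords, assignment, pts, labels = _random_instance(rng)
            res = silhouette_scores(coords, assignment, standardize=False)
            expected = brute_silhouette([tuple(p) for p in pts], list(labels))
            got = [res.per_contig[f"c{i}"] for i in range(len(pts))]
            assert np.allclose(got, expected, atol=1e-9)

    def test_matches_sklearn_cross_check(self, rng):
        coords, assignment, pts, labels = _random_instance(rng)
        if min(np.bincount(labels)) < 2:  # sklearn has no singleton convention
            labels[labels == labels.min()] = labels.max()
        assignment = {f"c{i}": f"bin{labels[i]}" for i in range(len(pts))}
        res = silhouette_scores(coords, assignment, standardize=False)
        ref = silhouette_samples(pts, labels)
        got = [res.per_contig[f"c{i}"] for i in range(len(pts))]
        assert np.allclose(got, ref, atol=1e-9)

    def test_singleton_bin_scores_zero(self):
        coords = {"a": (0, 0), "b": (1, 0), "s": (5, 5)}
        res = silhouette_scores(coords, {"a": "A", "b": "A", "s": "S"}, standardize=False)
        assert res.per_contig["s"] == 0.0

    def test_identical_coordinates_score_zero(self):
        coords = {f"c{i}": (1.0, 2.0) for i in range(6)}
        labels = {f"c{i}": "AB"[i % 2] for i in range(6)}
        res = silhouette_scores(coords, labels, standardize=False)
        assert all(v == 0.0 for v in res.per_contig.values())

    def test_fewer_than_two_bins_rejected(self):
        with pytest.raises(MetricError):
            silhouette_scores({"a": (0,), "b": (1,)}, {"a": "X", "b": "X"})

    def test_nonfinite_coordinate_names_contig(self):
        coords = {"a": (0.0,), "bad": (np.nan,), "c": (1.0,)}
        labels = {k: "AB"[i % 2] for i, k in enumerate(coords)}
        with pytest.raises(MetricError, match="bad"):
            silhouette_scores(coords, labels)

    def test_standardization_rescales_dominant_axis(self):
        # raw x-range dwarfs y; standardized distances weigh both equally
        coords = {"a": (0, 0), "b": (0, 1), "c": (1000, 0), "d": (1000, 1)}
        labels = {"a": "A", "b": "B", "c": "A", "d": "B"}
        raw = silhouette_scores(coords, labels, standardize=False)
        std = silhouette_scores(coords, labels, standardize=True)
        assert std.overall_mean > raw.overall_mean

    def test_subsampling_is_seeded_and_bounded(self, rng):
        coords, assignment, *_ = _random_instance(rng, n_max=60)
        r1 = silhouette_scores(coords, assignment, sample_size=20, seed=3)
        r2 = silhouette_scores(coords, assignment, sample_size=20, seed=3)
        assert r1.n_used == 20 and r1.per_contig == r2.per_contig


class TestAdjustedRand:
    def test_identical_plans_score_one(self):
        plan = {f"c{i}": f"b{i % 3}" for i in range(12)}
        assert adjusted_rand(plan, dict(plan)).ari == 1.0

    def test_worked_six_element_example(self):
        a = dict(zip("123456", "111222"))
        b = dict(zip("123456", "112222"))
        res = adjusted_rand(a, b)
        assert res.ari == pytest.approx(0.3243, abs=1e-4)
        assert res.n_shared == 6

    def test_one_bin_versus_singletons_is_zero(self):
        a = {f"c{i}": "all" for i in range(8)}
        b = {f"c{i}": f"s{i}" for i in range(8)}
        assert adjusted_rand(a, b).ari == 0.0

    def test_matches_bruteforce_and_sklearn(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            la = rng.integers(0, 5, size=n)
            lb = rng.integers(0, 5, size=n)
            a = {f"c{i}": f"x{la[i]}" for i in range(n)}
            b = {f"c{i}": f"y{lb[i]}" for i in range(n)}
            got = adjusted_rand(a, b).ari
            assert got == pytest.approx(brute_ari(list(la), list(lb)), abs=1e-12)
            assert got == pytest.approx(adjusted_rand_score(la, lb), abs=1e-9)

    def test_symmetric_and_relabel_invariant(self, rng):
        n = 30
        la = rng.integers(0, 4, size=n)
        lb = rng.integers(0, 3, size=n)
        a = {f"c{i}": f"x{la[i]}" for i in range(n)}
        b = {f"c{i}": f"y{lb[i]}" for i in range(n)}
        relabeled = {k: f"renamed_{v}" for k, v in a.items()}
        assert adjusted_rand(a, b).ari == pytest.approx(adjusted_rand(b, a).ari)
        assert adjusted_rand(relabeled, b).ari == pytest.approx(adjusted_rand(a, b).ari)

    def test_restricted_to_shared_contigs(self):
        a = {"c1": "A", "c2": "A", "c3": "B", "only_a": "B"}
        b = {"c1": "X", "c2": "X", "c3": "Y", "only_b": "Y"}
        res = adjusted_rand(a, b)
        assert res.n_shared == 3 and res.ari == 1.0

    def test_empty_intersection_rejected(self):
        with pytest.raises(MetricError):
            adjusted_rand({"a": "1"}, {"b": "2"})


class TestCompletenessRedundancy:
    @pytest.fixture
    def marker_table(self):
        rows = {
            "c1": {"m": "g1,g2,g2"},
            "c2": {"m": "g3"},
            "c3": {"m": "other"},
        }
        return build_table(rows, [ColumnSpec("m", "feature_set")])

    def test_worked_example(self, marker_table):
        group = FeatureGroup("g", ["g1", "g2", "g3", "g4"])
        assert completeness_redundancy(marker_table, None, group, "m") == (75.0, 25.0)

    def test_absent_and_complete_cases(self, marker_table):
        none = FeatureGroup("none", ["z1", "z2"])
        assert completeness_redundancy(marker_table, None, none, "m") == (0.0, 0.0)
        single = FeatureGroup("single", ["g1", "g3"])
        assert completeness_redundancy(marker_table, ["c1", "c2"], single, "m") == (100.0, 0.0)

    def test_masked_contigs_excluded(self, marker_table):
        group = FeatureGroup("g", ["g1", "g2", "g3", "g4"])
        set_flag(marker_table, {"c2"}, "mask", True)
        comp, red = completeness_redundancy(marker_table, None, group, "m")
        assert comp == 50.0

    def test_monotone_under_selection_growth(self, rng):
        members = [f"g{i}" for i in range(10)]
        group = FeatureGroup("g", members)
        rows = {
            f"c{i}": {"m": ",".join(rng.choice(members, size=rng.integers(0, 4)))}
            for i in range(30)
        }
        t = build_table(rows, [ColumnSpec("m", "feature_set")])
        prev = (0.0, 0.0)
        ids = []
        for cid in t.ids:
            ids.append(cid)
            cur = completeness_redundancy(t, ids, group, "m")
            assert cur[0] >= prev[0] and cur[1] >= prev[1]
            prev = cur

    def test_redundancy_can_exceed_100(self):
        t = build_table({"c1": {"m": ",".join(["g1"] * 5)}}, [ColumnSpec("m", "feature_set")])
        comp, red = completeness_redundancy(t, None, FeatureGroup("g", ["g1"]), "m")
        assert comp == 100.0 and red == 400.0


class TestQualityTiers:
    @pytest.mark.parametrize(
        "comp, cont, tier",
        [
            (95, 3, QualityTier.HIGH),
            (55, 8, QualityTier.MEDIUM),
            (30, 5, QualityTier.LOW),
            (80, 12, QualityTier.EXCLUDED),
            (90, 5, QualityTier.MEDIUM),  # high needs cont < 5
            (90, 4.99, QualityTier.HIGH),
            (49.99, 9.99, QualityTier.LOW),
            (100, 10, QualityTier.EXCLUDED),
        ],
    )
    def test_catalog_thresholds(self, comp, cont, tier):
        assert classify_quality(comp, cont) is tier

    def test_domain_partition(self):
        grid_c = [0, 25, 49.99, 50, 75, 89.99, 90, 100, 150]
        grid_k = [0, 4.99, 5, 9.99, 10, 50, 120]
        for c in grid_c:
            for k in grid_k:
                assert classify_quality(c, k) in QualityTier

    def test_negative_inputs_rejected(self):
        with pytest.raises(MetricError):
            classify_quality(-1, 0)


class TestCompareBins:
    LENGTHS = {"c1": 100, "c2": 300, "c3": 100}

    def test_identical_and_disjoint(self):
        res = compare_bins({"c1", "c2"}, {"c1", "c2"}, self.LENGTHS)
        assert (res.jaccard, res.containment_a_in_b, res.containment_b_in_a) == (1, 1, 1)
        res = compare_bins({"c1"}, {"c3"}, self.LENGTHS)
        assert res.jaccard == 0.0

    def test_length_weighted_worked_example(self):
        res = compare_bins({"c1", "c2"}, {"c2", "c3"}, self.LENGTHS)
        assert res.jaccard == pytest.approx(0.6)
        assert res.containment_a_in_b == pytest.approx(0.75)
        assert res.containment_b_in_a == pytest.approx(0.75)

    def test_unweighted_variant(self):
        res = compare_bins({"c1", "c2"}, {"c2", "c3"}, self.LENGTHS, weighted=False)
        assert res.jaccard == pytest.approx(1 / 3)

    def test_empty_union_rejected(self):
        with pytest.raises(MetricError):
            compare_bins(set(), set(), {})
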