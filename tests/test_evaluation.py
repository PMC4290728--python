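"""Evaluation metrics: frozen arithmetic examples, invariances, pair oracle."""

import itertools

import numpy as np
import pytest

from metaec.evaluation import (
    MetaLabels,
    composition_table,
    f_measure,
    f_score,
    gender_variation,
    neighborhood_affinity,
    pr_metric,
    reference_clusters,
)
from metaec.similarity import SimilarityMatrix
from metaec.symnmf import Community


def make_community(clusters, extra_unassigned=()):
    ids = sorted(set().union(*clusters) | set(extra_unassigned))
    return Community(ids, [set(c) for c in clusters], set(extra_unassigned))


@pytest.fixture
def six_class_reference():
    # six equal reference classes of 4 samples each
    return {f"c{k}": {f"s{k}_{i}" for i in range(4)} for k in range(6)}


def _perfect_detection(ref):
    return make_community(list(ref.values()))


class TestFMeasure:
    def test_perfect_detection_scores_one(self, six_class_reference):
        det = _perfect_detection(six_class_reference)
        assert f_measure(det, six_class_reference) == (1.0, 1.0, 1.0)

    def test_one_megacluster_fails_affinity(self, six_class_reference):
        # |C∩R|²/(|C||R|) = |R|/|C| = 4/24 = 1/6 < 0.25 for every class
        allsamples = set().union(*six_class_reference.values())
        det = make_community([allsamples])
        assert f_measure(det, six_class_reference, omega=0.25) == (0.0, 0.0, 0.0)

    def test_half_matched_formula(self, six_class_reference):
        ref = six_class_reference
        det = make_community(
            [ref["c0"], {"s1_0", "s2_0", "s3_0", "s4_0"}],
            extra_unassigned=set().union(*ref.values()) - ref["c0"] - {"s1_0", "s2_0", "s3_0", "s4_0"},
        )
        p, r, f = f_measure(det, ref, omega=0.25)
        assert p == pytest.approx(0.5)
        assert r == pytest.approx(1 / 6)
        assert f == pytest.approx(2 * 0.5 * (1 / 6) / (0.5 + 1 / 6))

    def test_empty_detection_rejected(self, six_class_reference):
        ids = sorted(set().union(*six_class_reference.values()))
        det = Community(ids, [], set(ids))
        with pytest.raises(ValueError):
            f_measure(det, six_class_reference)

    def test_affinity_formula(self):
        assert neighborhood_affinity({1, 2, 3}, {2, 3, 4, 5}) == pytest.approx(4 / 12)


class TestPRMetric:
    def test_perfect_detection_scores_one(self, six_class_reference):
        det = _perfect_detection(six_class_reference)
        assert pr_metric(det, six_class_reference) == pytest.approx(1.0)

    def test_all_singletons_scores_zero(self, six_class_reference):
        ids = sorted(set().union(*six_class_reference.values()))
        det = Community(ids, [{s} for s in ids], set())
        assert pr_metric(det, six_class_reference) == 0.0

    def test_merged_pair_of_classes_hand_enumeration(self):
        # 6 samples, reference {a,b,c} + {d,e,f}; detected merges them.
        ref = {"r1": {"a", "b", "c"}, "r2": {"d", "e", "f"}}
        det = make_community([{"a", "b", "c", "d", "e", "f"}])
        # detected pairs: all 15; reference pairs: 6; tp = 6
        p, r = 6 / 15, 6 / 6
        assert pr_metric(det, ref) == pytest.approx(2 * p * r / (p + r))

    def test_matches_bruteforce_pair_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            ids = [f"s{i}" for i in range(n)]
            ref_lab = rng.integers(0, 3, size=n)
            ref = {z: {ids[i] for i in np.flatnonzero(ref_lab == z)} for z in range(3)}
            ref = {z: c for z, c in ref.items() if c}
            k = int(rng.integers(1, 4))
            clusters = []
            for z in range(k):
                members = {ids[i] for i in np.flatnonzero(rng.random(n) < 0.5)}
                if members:
                    clusters.append(members)
            if not clusters:
                continue
            det = Community(ids, clusters, set(ids) - set().union(*clusters))

            tp = fp = fn = 0
            for a, b in itertools.combinations(ids, 2):
                in_det = any(a in c and b in c for c in clusters)
                in_ref = any(a in c and b in c for c in ref.values())
                tp += in_det and in_ref
                fp += in_det and not in_ref
                fn += in_ref and not in_det
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            want = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert pr_metric(det, ref) == pytest.approx(want, abs=1e-12)


class TestFScore:
    def test_perfect_detection_scores_one(self, six_class_reference):
        det = _perfect_detection(six_class_reference)
        assert f_score(det, six_class_reference) == pytest.approx(1.0)

    def test_union_of_two_equal_classes(self):
        ref = {"r1": {"a", "b"}, "r2": {"c", "d"}}
        det = make_community([{"a", "b", "c", "d"}])
        assert f_score(det, ref) == pytest.approx(2 / 3)

    def test_missing_class_contributes_zero(self):
        ref = {"r1": {"a", "b"}, "r2": {"c", "d"}}
        det = make_community([{"a", "b"}], extra_unassigned={"c", "d"})
        assert f_score(det, ref) == pytest.approx(0.5)  # (2*1 + 2*0) / 4


class TestMetricInvariances:
    def test_relabeling_invariance(self, six_class_reference):
        det = _perfect_detection(six_class_reference)
        shuffled = Community(det.sample_ids, det.clusters[::-1], set())
        for ref in (six_class_reference, dict(reversed(list(six_class_reference.items())))):
            assert f_measure(shuffled, ref)[2] == 1.0
            assert pr_metric(shuffled, ref) == pytest.approx(1.0)
            assert f_score(shuffled, ref) == pytest.approx(1.0)

    def test_scores_bounded_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            ids = [f"s{i}" for i in range(n)]
            ref_lab = rng.integers(0, 4, size=n)
            ref = {z: {ids[i] for i in np.flatnonzero(ref_lab == z)} for z in set(ref_lab)}
            clusters = [
                {ids[i] for i in np.flatnonzero(rng.random(n) < 0.4)} for _ in range(3)
            ]
            clusters = [c for c in clusters if c]
            if not clusters:
                continue
            det = Community(ids, clusters, set(ids) - set().union(*clusters))
            p, r, f = f_measure(det, ref)
            for v in (p, r, f, pr_metric(det, ref), f_score(det, ref)):
                assert 0.0 <= v <= 1.0


class TestMetaTables:
    @pytest.fixture
    def labels(self):
        habitat = {"m1": "gut", "m2": "gut", "f1": "gut", "f2": "skin", "f3": "oral"}
        gender = {"m1": "male", "m2": "male", "f1": "female", "f2": "female", "f3": "female"}
        return MetaLabels(habitat, gender)

    def test_composition_counts_hand_tally(self, labels):
        det = make_community([{"m1", "m2", "f1"}, {"f2", "f3"}])
        table = composition_table(det, labels)
        assert table.loc["cluster_0", "male&gut"] == 2
        assert table.loc["cluster_0", "female&gut"] == 1
        assert table.loc["cluster_0", "dominant"] == "male&gut"
        assert table.loc["cluster_1", "female&skin"] == 1
        assert table.loc["cluster_1", "female&oral"] == 1
        assert int(table.loc["cluster_0", list(table.columns[:-1])].sum()) == 3

    def test_unlabeled_sample_named_in_error(self, labels):
        det = make_community([{"m1", "ghost"}])
        with pytest.raises(KeyError, match="ghost"):
            composition_table(det, labels)

    def test_reference_clusters_partition_samples(self, labels):
        ref = reference_clusters(labels)
        assert set().union(*ref.values()) == set(labels.sample_ids)
        assert sum(len(c) for c in ref.values()) == len(labels.sample_ids)

    def test_unknown_habitat_rejected(self):
        with pytest.raises(ValueError, match="lung"):
            MetaLabels({"x": "lung"}, {"x": "male"})

    def test_gender_variation_hand_enumeration(self, labels):
        ids = ["m1", "m2", "f1", "f2", "f3"]
        rng = np.random.default_rng(1)
        A = rng.random((5, 5))
        M = np.clip((A + A.T) / 2, 0, 1)
        np.fill_diagonal(M, 1.0)
        m = SimilarityMatrix(ids, M)
        det = Community(ids, [{"m1", "m2", "f1", "f2"}], {"f3"})
        gv = gender_variation(det, m, labels)
        i = {s: k for k, s in enumerate(ids)}
        same = [M[i["m1"], i["m2"]], M[i["f1"], i["f2"]]]
        opp = [M[i["m1"], i["f1"]], M[i["m1"], i["f2"]],
               M[i["m2"], i["f1"]], M[i["m2"], i["f2"]]]
        assert gv.loc["cluster_0", "same_gender"] == pytest.approx(np.mean(same))
        assert gv.loc["cluster_0", "opposite_gender"] == pytest.approx(np.mean(opp))

    def test_gender_variation_absent_sides_are_nan(self, labels):
        ids = ["m1", "m2", "f1"]
        M = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.7], [0.8, 0.7, 1.0]])
        m = SimilarityMatrix(ids, M)
        males = Community(ids, [{"m1", "m2"}], {"f1"})
        gv = gender_variation(males, m, labels)
        assert gv.loc["cluster_0", "same_gender"] == pytest.approx(0.9)
        assert np.isnan(gv.loc["cluster_0", "opposite_gender"])
        mixed = Community(ids, [{"m1", "f1"}], {"m2"})
        gv = gender_variation(mixed, m, labels)
        assert np.isnan(gv.loc["cluster_0", "same_gender"])
        assert gv.loc["cluster_0", "opposite_gender"] == pytest.approx(0.8)
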