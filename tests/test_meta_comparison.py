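"""Term-set clustering, parameter over-representation and literature scores."""

import itertools
import math

import numpy as np
import pytest

from coexnet.meta_comparison import (LiteratureScore, TermAssignment,
                                     cluster_literature_scores,
                                     cluster_similarity_graph,
                                     jaccard_distance_matrix,
                                     literature_score_test,
                                     parameter_overrepresentation,
                                     read_assignments, write_assignments)


def _assign(i, terms, **params):
    return TermAssignment(f"r{i}", params, frozenset(terms))


class TestJaccard:
    @pytest.mark.parametrize("a, b, expected", [
        ({"A", "B"}, {"B", "C"}, 2 / 3),
        ({"A", "B"}, {"A", "B"}, 0.0),
        ({"A"}, {"B"}, 1.0),
        (set(), set(), 0.0),
    ])
    def test_pairwise_values(self, a, b, expected):
        d = jaccard_distance_matrix([_assign(0, a), _assign(1, b)])
        assert d[0, 1] == pytest.approx(expected)

    def test_metric_properties_on_random_triples(self, rng):
        terms = [f"T{i}" for i in range(12)]
        for trial in range(30):
            sets = [set(rng.choice(terms, int(rng.integers(0, 8)),
                                   replace=False)) for _ in range(3)]
            d = jaccard_distance_matrix([_assign(i, s)
                                         for i, s in enumerate(sets)])
            assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
            assert np.all((0 <= d) & (d <= 1))
            for i, j, k in itertools.permutations(range(3), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestClustering:
    def test_two_blocks(self):
        assigns = [_assign(i, {"A", "B"}) for i in range(4)] + \
                  [_assign(4 + i, {"X", "Y"}) for i in range(4)]
        labels = cluster_similarity_graph(jaccard_distance_matrix(assigns),
                                          seed=0)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_identical_sets_single_cluster(self):
        assigns = [_assign(i, {"A"}) for i in range(5)]
        labels = cluster_similarity_graph(jaccard_distance_matrix(assigns),
                                          seed=0)
        assert len(set(labels.tolist())) == 1

    def test_deterministic(self, rng):
        terms = [f"T{i}" for i in range(20)]
        assigns = [_assign(i, set(rng.choice(terms, 6, replace=False)))
                   for i in range(10)]
        d = jaccard_distance_matrix(assigns)
        assert np.array_equal(cluster_similarity_graph(d, seed=5),
                              cluster_similarity_graph(d, seed=5))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_similarity_graph(d)


def exact_hypergeom_upper(n_total, big_k, n_cluster, k):
    total = math.comb(n_total, n_cluster)
    fav = sum(math.comb(big_k, j) * math.comb(n_total - big_k, n_cluster - j)
              for j in range(k, min(big_k, n_cluster) + 1))
    return fav / total


class TestParameterOverrepresentation:
    def test_pure_cluster_minimal_p(self):
        assigns = [_assign(i, set(), algorithm="aracne") for i in range(4)] + \
                  [_assign(4 + i, set(), algorithm="clr") for i in range(4)]
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        out = parameter_overrepresentation(labels, assigns,
                                           categories=["algorithm"])
        tab = out[0].table
        p_aracne = tab[(tab.value == "aracne")]["p"].iloc[0]
        assert p_aracne == min(tab["p"])
        assert p_aracne == pytest.approx(exact_hypergeom_upper(8, 4, 4, 4))

    def test_proportional_value_p_near_one(self):
        assigns = [_assign(i, set(), algorithm=["a", "b"][i % 2])
                   for i in range(12)]
        labels = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        out = parameter_overrepresentation(labels, assigns,
                                           categories=["algorithm"])
        assert (out[0].table["p"] > 0.5).all()

    def test_matches_exact_enumeration(self, rng):
        values = ["x", "y", "z"]
        assigns = [_assign(i, set(), metric=str(rng.choice(values)))
                   for i in range(12)]
        labels = rng.integers(0, 3, size=12)
        out = parameter_overrepresentation(labels, assigns,
                                           categories=["metric"])
        for ce in out:
            for _, row in ce.table.iterrows():
                expected = exact_hypergeom_upper(int(row.N), int(row.K),
                                                 int(row.n), int(row.k))
                assert row.p == pytest.approx(expected, rel=1e-9)

    def test_single_valued_category_skipped(self):
        assigns = [_assign(i, set(), dataset="d1", algorithm=["a", "b"][i % 2])
                   for i in range(6)]
        labels = np.zeros(6, dtype=int)
        out = parameter_overrepresentation(labels, assigns,
                                           categories=["dataset", "algorithm"])
        assert set(out[0].table["category"]) == {"algorithm"}

    def test_planted_driver_recovered(self, rng):
        """A parameter value that determines the term set is flagged.

        Calibrated at 50/50 runs before freezing; three runs here."""
        terms = [f"T{i}" for i in range(200)]
        for run in range(3):
            rng_run = np.random.default_rng(run)
            signature = set(rng_run.choice(terms, 30, replace=False))
            assigns = []
            for i in range(48):
                algo = str(rng_run.choice(["aracne", "clr", "wgcna"]))
                if algo == "aracne":
                    tset = {t for t in signature if rng_run.random() > 0.1}
                else:
                    tset = set(rng_run.choice(terms, 25, replace=False))
                assigns.append(_assign(i, tset, algorithm=algo))
            labels = cluster_similarity_graph(
                jaccard_distance_matrix(assigns), seed=run)
            flagged = False
            for ce in parameter_overrepresentation(labels, assigns,
                                                   categories=["algorithm"]):
                tab = ce.table
                hit = tab[(tab.value == "aracne") & tab.significant]
                flagged |= len(hit) > 0
            assert flagged


class TestLiteratureScore:
    def test_clear_separation_small_p(self):
        assign = _assign(0, {"A", "B", "C"})
        counts = {"A": 1e4, "B": 1e4, "C": 1e4, "D": 1.0, "E": 1.0, "F": 1.0}
        score = literature_score_test(assign, set("ABCDEF"), counts)
        assert score.testable and score.t > 0 and score.p < 0.01

    def test_constant_counts_untestable(self):
        assign = _assign(0, {"A", "B", "C"})
        counts = {t: 5.0 for t in "ABCDEF"}
        score = literature_score_test(assign, set("ABCDEF"), counts)
        assert not score.testable

    def test_insufficient_terms_untestable(self):
        assign = _assign(0, {"A"})
        counts = {t: float(i) for i, t in enumerate("ABCD")}
        score = literature_score_test(assign, set("ABCD"), counts)
        assert not score.testable

    def test_exchangeable_counts_mean_p_half(self, rng):
        ps = []
        terms = [f"T{i}" for i in range(40)]
        for run in range(40):
            rng_run = np.random.default_rng(run)
            counts = {t: float(rng_run.integers(1, 1000)) for t in terms}
            sig = set(rng_run.choice(terms, 10, replace=False))
            score = literature_score_test(_assign(0, sig), set(terms), counts)
            ps.append(score.p)
        assert abs(np.mean(ps) - 0.5) < 0.15

    def test_welch_matches_direct_computation(self):
        from scipy import stats

        assign = _assign(0, {"A", "B", "C"})
        counts = {"A": 10.0, "B": 20.0, "C": 30.0,
                  "D": 1.0, "E": 2.0, "F": 3.0}
        score = literature_score_test(assign, set("ABCDEF"), counts)
        x = np.log10(np.array([10.0, 20.0, 30.0]) + 1)
        y = np.log10(np.array([1.0, 2.0, 3.0]) + 1)
        t, p = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        assert score.t == pytest.approx(float(t))
        assert score.p == pytest.approx(float(p))

    def test_cluster_literature_scores_expected_cluster(self):
        scores = [LiteratureScore(f"r{i}", t=3.0 + 0.1 * i, p=0.01)
                  for i in range(4)] + \
                 [LiteratureScore(f"r{4 + i}", t=-1.0 - 0.1 * i, p=0.8)
                  for i in range(4)]
        labels, expected = cluster_literature_scores(scores, seed=0)
        high = {labels[i] for i in range(4)}
        assert high == {expected}


def test_assignment_jsonl_roundtrip(tmp_path):
    assigns = [_assign(0, {"A", "B"}, algorithm="clr", metric="mi"),
               _assign(1, {"C"}, algorithm="wgcna")]
    path = tmp_path / "a.jsonl"
    write_assignments(assigns, path)
    back = read_assignments(path)
    assert [a.terms for a in back] == [a.terms for a in assigns]
    assert back[0].parameters["algorithm"] == "clr"
    assert back[1].parameters["metric"] == "n/a"  # completed annotation
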