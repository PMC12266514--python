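"""Similarity metrics and the three pruning algorithms vs independent oracles."""

import numpy as np
import pytest

from coexnet.network_inference import (CoexpressionNetwork, NetworkProvenance,
                                       SimilarityMatrix, aracne_network,
                                       assemble_time_point_inputs, clr_network,
                                       clr_scores, compute_similarity,
                                       consensus_network, dpi_prune,
                                       infer_network, register_backend,
                                       wgcna_network)
from coexnet.pseudobulk import PseudoBulkMatrix


def _pb(matrix, labels=None):
    matrix = np.asarray(matrix, dtype=float)
    labels = labels or ["t1"] * matrix.shape[0]
    return PseudoBulkMatrix(matrix, [f"p{i}" for i in range(matrix.shape[0])],
                            [f"G{i:02d}" for i in range(matrix.shape[1])],
                            np.array(labels, dtype=object), "time", "ignore_zeros")


def _sim(values, metric="mi", genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:02d}" for i in range(values.shape[0])]
    return SimilarityMatrix(genes, values, metric)


class TestSimilarity:
    def test_linear_relation_pearson_one(self, rng):
        x = rng.random(20)
        pb = _pb(np.column_stack([x, 2 * x + 1, rng.random(20)]))
        sim = compute_similarity(pb, metric="pearson")
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_monotone_relation_spearman_one_pearson_below(self, rng):
        x = rng.random(30) * 3
        pb = _pb(np.column_stack([x, np.exp(x), x + rng.random(30)]))
        assert compute_similarity(pb, metric="spearman").values[0, 1] == \
            pytest.approx(1.0)
        assert compute_similarity(pb, metric="pearson").values[0, 1] < 1.0

    def test_identical_balanced_binary_mi_is_one_bit(self):
        x = np.array([0.0, 1.0] * 10)
        pb = _pb(np.column_stack([x, x, 1 - x]))
        sim = compute_similarity(pb, metric="mi", n_bins=2)
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[0, 2] == pytest.approx(1.0)  # MI is sign-blind

    def test_constant_gene_correlations_zero_with_warning(self, rng):
        matrix = rng.random((10, 3))
        matrix[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            sim = compute_similarity(_pb(matrix), metric="pearson")
        assert sim.values[0, 1] == 0.0 and sim.values[1, 2] == 0.0

    def test_mi_matches_pairwise_recomputation(self, rng):
        """Blockwise MI equals an independent per-pair contingency count."""
        matrix = rng.random((25, 8))
        sim = compute_similarity(_pb(matrix), metric="mi", n_bins=5)
        from coexnet.network_inference import _binned_mi_pair, _equal_frequency_bins

        bins = _equal_frequency_bins(matrix, 5)
        for i in range(8):
            for j in range(i + 1, 8):
                expected = _binned_mi_pair(bins[:, i], bins[:, j], 5)
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-10)


class TestAssembleInputs:
    def test_combined_and_single(self, small_study):
        from coexnet.pseudobulk import make_pseudobulks

        pb = make_pseudobulks(small_study, "time", "ignore_zeros", seed=0)
        combined = assemble_time_point_inputs(pb, "combined")
        assert len(combined) == 1 and combined[0][1].n_pseudobulks == 30
        single = assemble_time_point_inputs(pb, "single")
        assert [lab for lab, _ in single] == ["t1", "t2", "t3"]
        assert all(sub.n_pseudobulks == 10 for _, sub in single)

    def test_small_label_skipped_with_warning(self, rng):
        pb = _pb(rng.random((7, 4)), ["t1"] * 5 + ["t2"] * 2)
        with pytest.warns(UserWarning, match="t2"):
            out = assemble_time_point_inputs(pb, "single")
        assert [lab for lab, _ in out] == ["t1"]


def dpi_oracle(values, genes, threshold, tolerance=0.0):
    """O(n^3) triplet scan over the thresholded graph."""
    n = len(genes)
    present = values > threshold
    np.fill_diagonal(present, False)
    kept = {}
    for i in range(n):
        for j in range(i + 1, n):
            if not present[i, j]:
                continue
            remove = False
            for k in range(n):
                if k in (i, j) or not (present[i, k] and present[j, k]):
                    continue
                if values[i, j] < min(values[i, k], values[j, k]) * (1 - tolerance):
                    remove = True
                    break
            if not remove:
                kept[(genes[i], genes[j])] = values[i, j]
    return kept


class TestAracne:
    def test_triangle_weakest_edge_removed(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.5
        values[1, 2] = values[2, 1] = 0.3
        values[0, 2] = values[2, 0] = 0.2
        net = aracne_network(_sim(values), threshold=0.1)
        assert net.has_edge("G00", "G01") and net.has_edge("G01", "G02")
        assert not net.has_edge("G00", "G02")

    def test_chain_without_triangle_untouched(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.5
        values[1, 2] = values[2, 1] = 0.3
        net = aracne_network(_sim(values), threshold=0.1)
        assert net.n_edges == 2

    def test_matches_triplet_oracle_and_idempotent(self, rng):
        for trial in range(5):
            raw = rng.random((20, 20))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0.0)
            sim = _sim(values)
            net = aracne_network(sim, threshold=0.4)
            expected = dpi_oracle(values, sim.genes, 0.4)
            assert net.edges == expected
            again = dpi_prune(net.edges, sim.genes)
            assert again == net.edges

    def test_requires_mi(self, rng):
        corr = np.eye(3)
        with pytest.raises(ValueError, match="mutual-information"):
            aracne_network(_sim(corr, metric="pearson"), threshold=0.1)

    def test_permutation_threshold_deterministic(self, rng):
        pb = _pb(rng.random((15, 10)))
        from coexnet.network_inference import mi_permutation_threshold

        t1 = mi_permutation_threshold(pb, pb.gene_ids, seed=4)
        t2 = mi_permutation_threshold(pb, pb.gene_ids, seed=4)
        assert t1 == t2 and t1 > 0


class TestCLR:
    def test_pair_at_row_means_scores_zero(self):
        # all off-diagonal MI equal -> every z is 0 -> no edges
        values = np.full((4, 4), 0.5)
        np.fill_diagonal(values, 0.0)
        net = clr_network(_sim(values), z_cutoff=0.5)
        assert net.n_edges == 0

    def test_single_strong_pair_has_max_score(self):
        values = np.full((5, 5), 0.2)
        np.fill_diagonal(values, 0.0)
        values[0, 1] = values[1, 0] = 2.0
        scores = clr_scores(values)
        off = scores[np.triu_indices(5, 1)]
        assert scores[0, 1] == off.max() > 0

    def test_matches_independent_recomputation(self, rng):
        raw = rng.random((15, 15))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        scores = clr_scores(values)
        for i in range(15):
            for j in range(15):
                if i == j:
                    continue
                row_i = np.delete(values[i], i)
                row_j = np.delete(values[j], j)
                zi = max(0.0, (values[i, j] - row_i.mean()) / row_i.std())
                zj = max(0.0, (values[i, j] - row_j.mean()) / row_j.std())
                assert scores[i, j] == pytest.approx(np.hypot(zi, zj), abs=1e-9)

    def test_zero_sd_row_handled(self):
        values = np.zeros((3, 3))
        net = clr_network(_sim(values), z_cutoff=0.1)
        assert net.n_edges == 0


class TestWGCNA:
    def test_beta_one_quantile_zero_keeps_all_nonzero(self, rng):
        raw = rng.random((6, 6)) - 0.5
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        net = wgcna_network(_sim(values, metric="pearson"), beta=1,
                            edge_quantile=0.0)
        nonzero = np.abs(values[np.triu_indices(6, 1)]) > 0
        assert net.n_edges == int(nonzero.sum())

    def test_adjacency_monotone_decreasing_in_beta(self, rng):
        raw = rng.random((8, 8)) * 0.9
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        sim = _sim(values, metric="pearson")
        w_low = wgcna_network(sim, beta=2, edge_quantile=0.5)
        w_high = wgcna_network(sim, beta=12, edge_quantile=0.5)
        assert all(w_high.edges[e] <= w_low.edges[e] + 1e-12
                   for e in w_high.edges if e in w_low.edges)

    def test_edge_count_matches_quantile_oracle(self, rng):
        raw = rng.random((12, 12))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        net = wgcna_network(_sim(values, metric="pearson"), beta=3,
                            edge_quantile=0.9)
        adjacency = np.abs(values) ** 3
        off = adjacency[~np.eye(12, dtype=bool)]
        cutoff = np.quantile(off, 0.9)
        expected = int((adjacency[np.triu_indices(12, 1)] > cutoff).sum())
        assert net.n_edges == expected

    def test_all_zero_similarity_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            net = wgcna_network(_sim(np.zeros((4, 4)), metric="pearson"))
        assert net.n_edges == 0


class TestConsensus:
    def _net(self, edges):
        genes = ["A", "B", "C", "D"]
        return CoexpressionNetwork(genes, {e: 1.0 for e in edges})

    def test_majority_rule(self):
        nets = [self._net({("A", "B"), ("B", "C")}),
                self._net({("A", "B"), ("C", "D")}),
                self._net({("A", "B"), ("B", "C")})]
        cons = consensus_network(nets)
        assert cons.has_edge("A", "B")          # 3/3
        assert cons.has_edge("B", "C")          # 2/3 > 0.5
        assert not cons.has_edge("C", "D")      # 1/3
        assert cons.provenance.algorithm == "consensus"

    def test_mean_weight(self):
        a = CoexpressionNetwork(["A", "B"], {("A", "B"): 1.0})
        b = CoexpressionNetwork(["A", "B"], {("A", "B"): 3.0})
        c = CoexpressionNetwork(["A", "B"], {})
        cons = consensus_network([a, b, c])
        assert cons.edges[("A", "B")] == pytest.approx(2.0)

    def test_gene_universe_mismatch_rejected(self):
        a = CoexpressionNetwork(["A", "B"], {})
        b = CoexpressionNetwork(["A", "C"], {})
        with pytest.raises(ValueError, match="universe"):
            consensus_network([a, b])


def test_backend_registry(small_study, rng):
    pb = _pb(rng.random((10, 5)))

    def fake_backend(pb_in, genes=None, metric=None, seed=0):
        return CoexpressionNetwork(list(pb_in.gene_ids), {},
                                   NetworkProvenance(algorithm="cscore"))

    register_backend("cscore", fake_backend)
    net = infer_network(pb, pb.gene_ids, "cscore")
    assert net.provenance.algorithm == "cscore"
    with pytest.raises(ValueError, match="requires metric"):
        infer_network(pb, pb.gene_ids, "aracne", metric="pearson")


def test_network_tsv_roundtrip(tmp_path):
    prov = NetworkProvenance(dataset="d", algorithm="clr", metric="mi")
    net = CoexpressionNetwork(["A", "B", "C"], {("A", "B"): 1.5}, prov)
    path = tmp_path / "net.tsv"
    net.write_tsv(path)
    from coexnet.cli import _read_network

    back = _read_network(str(path))
    assert back.edges == net.edges
    assert back.provenance == prov
    assert set(back.genes) == {"A", "B", "C"}
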