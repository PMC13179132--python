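"""Co-regulation network: all-pairs streaming, null, filtering, annotation."""

import numpy as np
import pandas as pd
import pytest

from protempo import network, preprocess, simulate
from protempo.datatypes import (
    CorrelationNetwork,
    GeneSet,
    GeneSetCollection,
    ValidationError,
)
from protempo.simulate import ModuleSpec, SyntheticConfig
from protempo.stats import pearson_p_from_r

from conftest import make_matrix


def collect_pairs(matrix, **kwargs):
    ii, jj, rr = [], [], []
    for i, j, r in network.pairwise_correlations(matrix, **kwargs):
        ii.append(i); jj.append(j); rr.append(r)
    return (np.concatenate(ii), np.concatenate(jj), np.concatenate(rr))


class TestPairwiseCorrelations:
    def test_pair_universe_count(self):
        assert network.count_pairs(6261) == 19_596_930
        assert network.count_pairs(4) == 6

    def test_r_matches_naive_formula(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 9))
        mat = make_matrix(vals, n_stages=3, n_reps=3, scale="log2_ratio")
        ii, jj, rr = collect_pairs(mat, block_size=2)  # force multi-block path
        assert len(rr) == network.count_pairs(6)
        for i, j, r in zip(ii, jj, rr):
            x, y = vals[i], vals[j]
            naive = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert r == pytest.approx(naive, abs=1e-12)

    def test_duplicated_rows_give_r_one(self):
        vals = np.vstack([np.arange(9.0), np.arange(9.0)])
        mat = make_matrix(vals, n_stages=3, n_reps=3, scale="log2_ratio")
        _, _, rr = collect_pairs(mat)
        assert rr[0] == pytest.approx(1.0)

    def test_zero_variance_features_emitted_undefined(self):
        vals = np.vstack([np.ones(9), np.arange(9.0)])
        mat = make_matrix(vals, n_stages=3, n_reps=3, scale="log2_ratio")
        _, _, rr = collect_pairs(mat)
        assert np.isnan(rr[0])

    def test_fewer_than_three_samples_rejected(self):
        mat = make_matrix(np.ones((3, 2)), n_stages=1, n_reps=2,
                          scale="log2_ratio")
        with pytest.raises(ValidationError):
            next(network.pairwise_correlations(mat))


class TestPermutationNull:
    def test_default_draw_count(self):
        rng = np.random.default_rng(0)
        mat = make_matrix(rng.normal(size=(400, 9)), n_stages=3, n_reps=3,
                          scale="log2_ratio")
        null = network.permutation_null(mat, n_pairs=500, n_shuffles=10, seed=1)
        assert null.r.size == 5000

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(1)
        mat = make_matrix(rng.normal(size=(300, 9)), n_stages=3, n_reps=3,
                          scale="log2_ratio")
        null = network.permutation_null(mat, n_pairs=2000, n_shuffles=5, seed=2)
        se = null.r.std() / np.sqrt(null.r.size)
        assert abs(null.r.mean()) < 3 * se + 1e-3

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        mat = make_matrix(rng.normal(size=(50, 9)), n_stages=3, n_reps=3,
                          scale="log2_ratio")
        a = network.permutation_null(mat, n_pairs=100, n_shuffles=3, seed=5)
        b = network.permutation_null(mat, n_pairs=100, n_shuffles=3, seed=5)
        np.testing.assert_array_equal(a.r, b.r)

    def test_capped_when_pairs_exhausted(self, caplog):
        rng = np.random.default_rng(3)
        mat = make_matrix(rng.normal(size=(5, 9)), n_stages=3, n_reps=3,
                          scale="log2_ratio")
        with caplog.at_level("WARNING"):
            null = network.permutation_null(mat, n_pairs=1000, n_shuffles=2,
                                            seed=1)
        assert null.r.size == 2 * network.count_pairs(5)

    def test_constant_data_drops_all_correlations(self):
        mat = make_matrix(np.ones((10, 9)), n_stages=3, n_reps=3,
                          scale="log2_ratio")
        null = network.permutation_null(mat, n_pairs=10, n_shuffles=2, seed=0)
        assert null.r.size == 0
        assert null.n_dropped == 2 * 10


class TestBuildNetwork:
    def test_r_gate_excludes_strong_p(self):
        # r = 0.94 with tiny p is still excluded: both criteria must hold
        feats = ["A", "B"]
        pairs = [(np.array([0]), np.array([1]), np.array([0.94]))]
        net = network.build_network(pairs, feats, n_samples=100,
                                    r_min=0.95, alpha=0.01)
        assert net.n_edges == 0

    def test_noiseless_module_fully_recovered_positive(self):
        cfg = SyntheticConfig(
            modules=[ModuleSpec("m", 5, (0.0, 1.0, 2.0), 0.0)],
            anticorrelated_pairs=[], cooperative=[], n_background=5,
            n_background_clusters=0, replicate_sd=0.0, seed=0)
        prot, truth = simulate.generate_proteome(cfg)
        norm = preprocess.normalize_to_geometric_mean(prot)
        net = network.correlation_network(norm)
        members = set(truth.module_members["m"])
        within = net.edges[net.edges["protein_a"].isin(members)
                           & net.edges["protein_b"].isin(members)]
        assert len(within) == 10
        assert (within["sign"] == "positive").all()

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(12, 9))
        mat = make_matrix(vals, n_stages=3, n_reps=3, scale="log2_ratio")
        net = network.correlation_network(mat, r_min=0.5, alpha=0.2)
        # brute force: full r matrix, t-transform p, BH over all pairs
        from protempo.stats import bh_adjust
        r_full = np.corrcoef(vals)
        iu, ju = np.triu_indices(12, k=1)
        r = r_full[iu, ju]
        p_adj = bh_adjust(pearson_p_from_r(r, 9))
        keep = (np.abs(r) >= 0.5) & (p_adj < 0.2)
        expect = {
            frozenset((mat.features[i], mat.features[j]))
            for i, j, k in zip(iu, ju, keep) if k
        }
        got = {frozenset((a, b))
               for a, b in zip(net.edges["protein_a"], net.edges["protein_b"])}
        assert got == expect

    def test_edge_set_invariant_under_row_permutation(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(10, 9))
        mat = make_matrix(vals, n_stages=3, n_reps=3, scale="log2_ratio")
        net1 = network.correlation_network(mat, r_min=0.4, alpha=0.5)
        perm = rng.permutation(10)
        mat2 = make_matrix(vals[perm],
                           features=[mat.features[i] for i in perm],
                           n_stages=3, n_reps=3, scale="log2_ratio")
        net2 = network.correlation_network(mat2, r_min=0.4, alpha=0.5)
        key = ["protein_a", "protein_b"]
        pd.testing.assert_frame_equal(
            net1.edges.sort_values(key).reset_index(drop=True),
            net2.edges.sort_values(key).reset_index(drop=True),
        )


def _net(edge_pairs, nodes=None, r=0.99):
    rows = []
    for a, b in edge_pairs:
        a, b = sorted((a, b))
        rows.append({"protein_a": a, "protein_b": b, "r": r, "p_raw": 1e-9,
                     "p_adj": 1e-7, "sign": "positive" if r > 0 else "negative"})
    return CorrelationNetwork(pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "r", "p_raw", "p_adj", "sign"]),
        nodes=nodes)


class TestDegreeStats:
    def test_triangle(self):
        mean, sd, deg = network.degree_stats(_net([("A", "B"), ("B", "C"),
                                                   ("A", "C")]))
        assert (mean, sd) == (2.0, 0.0)

    def test_star_of_four_leaves(self):
        mean, sd, deg = network.degree_stats(
            _net([("H", "L1"), ("H", "L2"), ("H", "L3"), ("H", "L4")]))
        assert sorted(deg) == [1, 1, 1, 1, 4]
        assert mean == pytest.approx(1.6)

    def test_handshake_lemma_random_graphs(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            names = [f"N{i}" for i in range(10)]
            pairs = {tuple(sorted(rng.choice(names, 2, replace=False)))
                     for _ in range(15)}
            net = _net(list(pairs))
            _, _, deg = network.degree_stats(net)
            assert deg.sum() == 2 * net.n_edges

    def test_empty_network_warns_zeros(self, caplog):
        net = _net([], nodes=frozenset({"A", "B"}))
        with caplog.at_level("WARNING"):
            mean, sd, deg = network.degree_stats(net)
        assert (mean, sd) == (0.0, 0.0)


class TestAnnotation:
    def _coll(self, **sets):
        return GeneSetCollection({
            n: GeneSet(n, frozenset(m), "complex") for n, m in sets.items()
        })

    def test_shared_complex_annotates_edge(self):
        net = _net([("A", "B"), ("A", "C")])
        ann = network.annotate_edges(net, {"complex": self._coll(c1={"A", "B"})})
        flags = dict(zip(zip(ann["protein_a"], ann["protein_b"]), ann["complex"]))
        assert flags[("A", "B")] and not flags[("A", "C")]

    def test_toy_flags_match_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        names = [f"N{i}" for i in range(8)]
        pairs = list({tuple(sorted(rng.choice(names, 2, replace=False)))
                      for _ in range(12)})
        sets = {f"s{k}": set(rng.choice(names, 3, replace=False))
                for k in range(4)}
        net = _net(pairs)
        coll = self._coll(**sets)
        ann = network.annotate_edges(net, {"complex": coll})
        for _, row in ann.iterrows():
            expect = any(row["protein_a"] in s and row["protein_b"] in s
                         for s in sets.values())
            assert row["complex"] == expect

    def test_enrichment_ratio_hand_example(self):
        # 10 nodes, 5 observed edges of which 2 annotated;
        # 45 possible pairs of which 9 annotated -> (2/5)/(9/45) = 2.0
        nodes = frozenset(f"N{i}" for i in range(10))
        observed = [("N0", "N1"), ("N2", "N3"), ("N0", "N5"), ("N4", "N8"),
                    ("N8", "N9")]
        net = _net(observed, nodes=nodes)
        coll = GeneSetCollection({
            "s1": GeneSet("s1", frozenset({"N0", "N1"}), "complex"),
            "s2": GeneSet("s2", frozenset({"N2", "N3"}), "complex"),
            "s3": GeneSet("s3", frozenset({"N4", "N5", "N6", "N7"}), "complex"),
            "s4": GeneSet("s4", frozenset({"N8", "N0"}), "complex"),
        })
        # pairs: N0N1, N2N3, 6 within s3, N0N8 -> 9 annotated possible pairs
        # observed annotated: N0-N1 and N2-N3 -> 2 of 5
        ratio = network.annotation_enrichment_ratio(net, coll)
        assert ratio == pytest.approx((2 / 5) / (9 / 45))

    def test_every_pair_annotated_ratio_one(self):
        nodes = frozenset({"A", "B", "C"})
        net = _net([("A", "B")], nodes=nodes)
        coll = self._coll(allset={"A", "B", "C"})
        assert network.annotation_enrichment_ratio(net, coll) == pytest.approx(1.0)

    def test_random_observed_edges_ratio_near_one(self):
        rng = np.random.default_rng(8)
        names = [f"N{i}" for i in range(30)]
        coll = self._coll(**{f"s{k}": set(rng.choice(names, 5, replace=False))
                             for k in range(6)})
        ratios = []
        from itertools import combinations
        all_pairs = list(combinations(names, 2))
        for _ in range(40):
            idx = rng.choice(len(all_pairs), 60, replace=False)
            net = _net([all_pairs[i] for i in idx], nodes=frozenset(names))
            ratios.append(network.annotation_enrichment_ratio(net, coll))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)


class TestComplexRecovery:
    def test_fully_connected_planted_complex(self):
        members = {"A", "B", "C", "D"}
        from itertools import combinations
        net = _net(list(combinations(sorted(members), 2)))
        gs = GeneSet("cpx", frozenset(members), "complex")
        rec = network.complex_recovery(net, gs)
        assert rec["n_members_in_network"] == 4
        assert rec["pct_possible_edges_present"] == 100.0
        assert rec["pct_edges_positive"] == 100.0

    def test_absent_complex_skipped(self):
        net = _net([("A", "B")])
        gs = GeneSet("cpx", frozenset({"X", "Y", "Z"}), "complex")
        assert network.complex_recovery(net, gs) is None

    def test_hand_counted_fractions(self):
        net = _net([("A", "B"), ("B", "C"), ("A", "D")])
        gs = GeneSet("cpx", frozenset({"A", "B", "C", "E"}), "complex")
        rec = network.complex_recovery(net, gs)
        assert rec["n_members_in_network"] == 3
        assert rec["pct_possible_edges_present"] == pytest.approx(100 * 2 / 3)


class TestMeanSetCorrelation:
    def test_identical_profiles_one(self):
        vals = np.vstack([np.arange(9.0), np.arange(9.0)])
        mat = make_matrix(vals, n_stages=3, n_reps=3, scale="log2_ratio")
        assert network.mean_set_correlation(mat, mat.features) == \
               pytest.approx(1.0)

    def test_hand_computed_mean_third(self):
        # profiles with pairwise r = (1, 0, 0) -> mean 1/3
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = x.copy()
        z = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to x
        vals = np.vstack([x, y, z])
        mat = make_matrix(vals, n_stages=1, n_reps=4, scale="log2_ratio")
        assert network.mean_set_correlation(mat, mat.features) == \
               pytest.approx(1 / 3, abs=1e-12)

    def test_single_member_undefined(self):
        mat = make_matrix(np.arange(9.0)[None, :], n_stages=3, n_reps=3,
                          scale="log2_ratio")
        assert np.isnan(network.mean_set_correlation(mat, mat.features))
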