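import numpy as np
import pytest

from lmdti.hetnet import (
    INTERACTION,
    SIMILARITY,
    build_heterogeneous_network,
    drop_ncrna_layers,
    dti_subnetwork,
    filter_similarity_edges,
)
from lmdti.netio import InteractionNetwork, SimilarityMatrix


def empty_net(sk, tk):
    return InteractionNetwork(sk, tk, [], [], set())


def make_layers(**overrides):
    layers = {
        "dti": empty_net("drug", "target"),
        "dl": empty_net("drug", "lncRNA"),
        "dm": empty_net("drug", "miRNA"),
        "lt": empty_net("lncRNA", "target"),
        "mt": empty_net("miRNA", "target"),
        "lm": empty_net("lncRNA", "miRNA"),
    }
    layers.update(overrides)
    return layers


def empty_sim(kind):
    return SimilarityMatrix(kind, [], np.zeros((0, 0)))


class TestFilterSimilarityEdges:
    def test_nothing_above_zero(self):
        sim = SimilarityMatrix("drug", ["a", "b"], np.eye(2))
        assert filter_similarity_edges(sim, 0.0) == []

    def test_count_forced_by_threshold(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.4
        v[0, 2] = v[2, 0] = 0.6
        v[1, 2] = v[2, 1] = 0.9
        sim = SimilarityMatrix("drug", ["a", "b", "c"], v)
        assert len(filter_similarity_edges(sim, 0.5)) == 2

    def test_threshold_one_rejected(self):
        sim = SimilarityMatrix("drug", ["a"], np.ones((1, 1)))
        with pytest.raises(ValueError):
            filter_similarity_edges(sim, 1.0)

    def test_edge_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(8)
        v = rng.random((20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        sim = SimilarityMatrix("drug", [f"d{i}" for i in range(20)], v)
        counts = [len(filter_similarity_edges(sim, tau)) for tau in np.linspace(0, 0.99, 12)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBuildNetwork:
    def test_all_empty_inputs_give_empty_graph(self):
        g = build_heterogeneous_network(empty_sim("drug"), empty_sim("target"), **make_layers())
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_three_node_construction(self):
        v = np.array([[1.0, 0.8], [0.8, 1.0]])
        dd = SimilarityMatrix("drug", ["d1", "d2"], v)
        tt = SimilarityMatrix("target", ["t1"], np.ones((1, 1)))
        dti = InteractionNetwork("drug", "target", ["d1"], ["t1"], {("d1", "t1")})
        g = build_heterogeneous_network(dd, tt, **make_layers(dti=dti))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g["d1"]["d2"]["edge_class"] == SIMILARITY
        assert g["d1"]["d2"]["weight"] == 0.8
        assert g["d1"]["t1"]["edge_class"] == INTERACTION
        assert g["d1"]["t1"]["weight"] == 1.0

    def test_kind_conflict_rejected(self):
        dd = SimilarityMatrix("drug", ["x1"], np.ones((1, 1)))
        tt = SimilarityMatrix("target", ["x1"], np.ones((1, 1)))
        with pytest.raises(ValueError, match="two kinds"):
            build_heterogeneous_network(dd, tt, **make_layers())

    def test_planted_network_bookkeeping(self, planted_default):
        """Node count equals the entity universes; per-class edge counts match the generator."""
        dd, tt, layers, truth = planted_default
        g = build_heterogeneous_network(dd, tt, **layers)
        assert g.number_of_nodes() == dd.n + tt.n + 20 + 20
        inter = [e for e in g.edges(data=True) if e[2]["edge_class"] == INTERACTION]
        sim = [e for e in g.edges(data=True) if e[2]["edge_class"] == SIMILARITY]
        assert len(inter) == sum(truth.edge_counts.values())
        n_sim_expected = len(filter_similarity_edges(dd, 0.0)) + len(filter_similarity_edges(tt, 0.0))
        assert len(sim) == n_sim_expected

    def test_constituent_layers_recoverable(self, planted_small):
        """The (kind-pair, edge-class) partition recovers each input layer exactly."""
        dd, tt, layers, _ = planted_small
        g = build_heterogeneous_network(dd, tt, **layers)
        kind_pairs = {
            "dti": {"drug", "target"}, "dl": {"drug", "lncRNA"}, "dm": {"drug", "miRNA"},
            "lt": {"lncRNA", "target"}, "mt": {"miRNA", "target"}, "lm": {"lncRNA", "miRNA"},
        }
        total = 0
        for name, kinds in kind_pairs.items():
            got = {
                frozenset((u, v))
                for u, v, d in g.edges(data=True)
                if d["edge_class"] == INTERACTION and {g.kind_of(u), g.kind_of(v)} == kinds
            }
            want = {frozenset(e) for e in layers[name].edges}
            assert got == want
            total += len(got)
        assert total == sum(1 for *_, d in g.edges(data=True) if d["edge_class"] == INTERACTION)


class TestDTISubnetwork:
    def test_ncrna_nodes_excluded(self):
        dd = SimilarityMatrix("drug", ["d1"], np.ones((1, 1)))
        tt = SimilarityMatrix("target", ["t1"], np.ones((1, 1)))
        lm = InteractionNetwork("lncRNA", "miRNA", ["l1"], ["m1"], {("l1", "m1")})
        g = build_heterogeneous_network(dd, tt, **make_layers(lm=lm))
        sub = dti_subnetwork(g)
        assert sub.drug_ids == ["d1"] and sub.target_ids == ["t1"]
        assert sub.Sd.item() == 0 and sub.St.item() == 0 and sub.A.item() == 0

    def test_three_node_extraction(self):
        v = np.array([[1.0, 0.8], [0.8, 1.0]])
        dd = SimilarityMatrix("drug", ["d1", "d2"], v)
        tt = SimilarityMatrix("target", ["t1"], np.ones((1, 1)))
        dti = InteractionNetwork("drug", "target", ["d1"], ["t1"], {("d1", "t1")})
        g = build_heterogeneous_network(dd, tt, **make_layers(dti=dti))
        sub = dti_subnetwork(g)
        i1, i2 = sub.drug_ids.index("d1"), sub.drug_ids.index("d2")
        assert sub.A[i1, 0] == 1 and sub.A[i2, 0] == 0
        assert sub.Sd[i1, i2] == 0.8 and sub.Sd[i1, i1] == 0

    def test_no_drugs_rejected(self):
        tt = SimilarityMatrix("target", ["t1"], np.ones((1, 1)))
        g = build_heterogeneous_network(empty_sim("drug"), tt, **make_layers())
        with pytest.raises(ValueError):
            dti_subnetwork(g)

    def test_build_extract_round_trip(self, planted_small):
        """Extraction reproduces the thresholded similarities and interactions exactly."""
        dd, tt, layers, _ = planted_small
        tau = 0.3
        g = build_heterogeneous_network(dd, tt, **layers, sim_threshold=tau)
        sub = dti_subnetwork(g)
        di = {d: k for k, d in enumerate(sub.drug_ids)}
        ti = {t: k for k, t in enumerate(sub.target_ids)}
        want_sd = dd.values.copy()
        want_sd[want_sd <= tau] = 0.0
        np.fill_diagonal(want_sd, 0.0)
        perm_d = [di[d] for d in dd.ids]
        assert np.allclose(sub.Sd[np.ix_(perm_d, perm_d)], want_sd)
        want_a = np.zeros((dd.n, tt.n))
        for d, t in layers["dti"].edges:
            want_a[dd.ids.index(d), tt.ids.index(t)] = 1
        perm_t = [ti[t] for t in tt.ids]
        assert np.array_equal(sub.A[np.ix_(perm_d, perm_t)], want_a)


def test_drop_ncrna_layers(planted_small):
    dd, tt, layers, _ = planted_small
    g = build_heterogeneous_network(dd, tt, **layers)
    h = drop_ncrna_layers(g)
    assert {h.kind_of(n) for n in h.nodes} == {"drug", "target"}
    # drug-target structure unchanged
    assert dti_subnetwork(h).A.sum() == dti_subnetwork(g).A.sum()
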