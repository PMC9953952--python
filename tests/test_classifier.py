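"""Graph classifier: training, scoring, threshold, and edge attribution."""

import numpy as np
import pytest

from kgxplain.classifier import (
    ClassifierConfig,
    GraphHashModel,
    classify,
    edge_contributions,
    node_contributions,
    predict,
    train,
)
from kgxplain.features import build_feature_graph
from kgxplain.kg import KGEdge

from .conftest import cosmic_for, dbnsfp_for, make_variant, toy_world


def planted_graphs(n, seed, noise_cosmic=True):
    """Feature graphs whose label is planted solely in the SIFT score edge."""
    rng = np.random.default_rng(seed)
    variants, dbnsfp, cosmic, labels = [], [], [], []
    for i in range(n):
        v = make_variant(chrom=str(i % 10 + 1), pos=10_000 * (i + 1), gene=f"G{i}")
        label = i % 2
        score = rng.uniform(0.6, 0.95) if label else rng.uniform(0.05, 0.4)
        variants.append(v)
        dbnsfp.append(dbnsfp_for(v, {"SIFT": round(float(score), 6)}))
        if noise_cosmic:
            cosmic.append(cosmic_for(v, None, int(rng.integers(1, 1000))))
        labels.append("pathogenic" if label else "benign")
    kg, index = toy_world(variants, dbnsfp=dbnsfp, cosmic=cosmic)
    graphs = [build_feature_graph(v.key, kg, "estimation", index) for v in variants]
    return graphs, labels


class TestTrainPredict:
    def test_separable_pair_classified_correctly(self):
        graphs, labels = planted_graphs(2, seed=0, noise_cosmic=False)
        model = train(graphs, labels, ClassifierConfig(seed=0))
        for g, lab in zip(graphs, labels):
            assert classify(predict(model, g)) == lab

    def test_deterministic_given_seed(self):
        graphs, labels = planted_graphs(20, seed=1)
        m1 = train(graphs, labels, ClassifierConfig(seed=5))
        m2 = train(graphs, labels, ClassifierConfig(seed=5))
        assert [predict(m1, g) for g in graphs] == [predict(m2, g) for g in graphs]

    def test_single_class_rejected(self):
        graphs, _ = planted_graphs(4, seed=2)
        with pytest.raises(ValueError):
            train(graphs, ["pathogenic"] * 4)

    def test_planted_signal_training_auc(self):
        from kgxplain.evaluation import compute_metrics

        graphs, labels = planted_graphs(400, seed=3)
        model = train(graphs, labels, ClassifierConfig(seed=3))
        report = compute_metrics([predict(model, g) for g in graphs], labels)
        assert report.auc >= 0.9

    def test_scores_in_unit_interval_and_hub_only_graph_ok(self):
        graphs, labels = planted_graphs(10, seed=4)
        model = train(graphs, labels)
        for g in graphs:
            assert 0.0 <= predict(model, g) <= 1.0
        v = make_variant(chrom="20", pos=5, gene="EMPTY")
        kg, index = toy_world([v])
        bare = build_feature_graph(v.key, kg, "estimation", index)
        assert 0.0 <= predict(model, bare) <= 1.0

    def test_memorized_pathogenic_graph_scores_high(self):
        graphs, labels = planted_graphs(30, seed=5)
        model = train(graphs, labels, ClassifierConfig(seed=5))
        idx = labels.index("pathogenic")
        assert predict(model, graphs[idx]) >= 0.5

    def test_mode_mismatch_rejected(self):
        graphs, labels = planted_graphs(4, seed=6)
        model = train(graphs, labels)
        v = make_variant(chrom="21", pos=7, gene="X")
        kg, index = toy_world([v])
        wrong = build_feature_graph(v.key, kg, "explanation", index)
        with pytest.raises(ValueError):
            predict(model, wrong)

    def test_gnn_backend_unavailable(self):
        with pytest.raises(NotImplementedError):
            ClassifierConfig(backend="gnn")

    def test_model_json_round_trip(self, tmp_path):
        graphs, labels = planted_graphs(10, seed=7)
        model = train(graphs, labels)
        path = tmp_path / "model.json"
        model.to_json(str(path))
        back = GraphHashModel.from_json(str(path))
        assert predict(back, graphs[0]) == predict(model, graphs[0])


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.5, "pathogenic"), (0.499, "benign"), (1.0, "pathogenic"), (0.0, "benign")],
    )
    def test_threshold(self, score, expected):
        assert classify(score) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify(1.5)


def exact_surrogate(model, fg):
    """Independent oracle: normal-equations least squares over all 2^E masks."""
    from kgxplain.classifier import _edge_feature_matrix

    edges, phi = _edge_feature_matrix(fg, model.config.hash_dim)
    E = len(edges)
    masks = ((np.arange(2**E)[:, None] >> np.arange(E)) & 1).astype(float)
    y = np.array(
        [model.score_vector(phi[m.astype(bool)].sum(axis=0)) if m.any()
         else model.score_vector(np.zeros(phi.shape[1]))
         for m in masks]
    )
    X = np.hstack([np.ones((len(masks), 1)), masks])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return dict(zip(edges, beta[1:]))


class TestAttribution:
    def test_exhaustive_matches_exact_least_squares(self):
        graphs, labels = planted_graphs(20, seed=8)
        model = train(graphs, labels, ClassifierConfig(seed=8))
        fg = graphs[0]
        assert len(fg.graph.edges) <= 10
        got = edge_contributions(model, fg, n_perturbations=2048, seed=8)
        want = exact_surrogate(model, fg)
        assert set(got) == set(want)
        assert max(abs(got[e] - want[e]) for e in got) < 1e-6

    def test_null_edge_gets_zero_contribution(self):
        graphs, labels = planted_graphs(20, seed=9)
        model = train(graphs, labels, ClassifierConfig(seed=9))
        fg = graphs[0]
        contribs = edge_contributions(model, fg, n_perturbations=4096, seed=9)
        # the in_gene edge emits no token, so masking it cannot move the score
        null_edges = [e for e in contribs if e.predicate == "in_gene"]
        assert null_edges
        for e in null_edges:
            assert abs(contribs[e]) < 1e-9

    def test_single_edge_graph_contribution_is_score_delta(self):
        v = make_variant(chrom="5", pos=100, gene="Y")
        variants = [v]
        dbn = [dbnsfp_for(v, {"SIFT": 0.9})]
        kg, index = toy_world(variants, dbnsfp=dbn)
        graphs, labels = planted_graphs(20, seed=10)
        model = train(graphs, labels, ClassifierConfig(seed=10))
        fg = build_feature_graph(v.key, kg, "estimation", index)
        # keep only the score edge: build a single-edge graph by hand
        from kgxplain.features import FeatureGraph

        single = FeatureGraph(v.key, "estimation")
        hub = single.graph.get_or_create_hub(v.key, "variant")
        rid = f"dbnsfp:{v.key}"
        for nid in (rid, f"dbnsfp:{v.key}:SIFT"):
            single.graph.add_node(fg.graph.nodes[nid])
        e = single.graph.add_edge(rid, "SIFT", f"dbnsfp:{v.key}:SIFT")
        single.edge_roles[e] = "target"
        contribs = edge_contributions(model, single, seed=10)
        empty = FeatureGraph(v.key, "estimation")
        empty.graph.get_or_create_hub(v.key, "variant")
        delta = predict(model, single) - predict(model, empty)
        assert contribs[e] == pytest.approx(delta, abs=1e-9)

    def test_empty_graph_empty_map(self):
        graphs, labels = planted_graphs(4, seed=11)
        model = train(graphs, labels)
        v = make_variant(chrom="22", pos=9, gene="Z")
        kg, index = toy_world([v])
        fg = build_feature_graph(v.key, kg, "estimation", index)
        assert edge_contributions(model, fg) == {}

    def test_sampled_mode_deterministic_per_seed(self):
        graphs, labels = planted_graphs(40, seed=12)
        # a graph with many edges forces the sampled (non-exhaustive) path
        model = train(graphs, labels, ClassifierConfig(seed=12))
        big = max(graphs, key=lambda g: len(g.graph.edges))
        a = edge_contributions(model, big, n_perturbations=64, seed=3)
        b = edge_contributions(model, big, n_perturbations=64, seed=3)
        assert a == b


class TestNodeContributions:
    def _fg_two_edges(self):
        from kgxplain.features import FeatureGraph
        from kgxplain.kg import KGNode

        fg = FeatureGraph("1:1:A>T", "estimation")
        for nid in ("a", "b", "c", "iso"):
            fg.graph.add_node(KGNode(nid, "publication", nid, "none"))
        e1 = fg.graph.add_edge("a", "p", "b")
        e2 = fg.graph.add_edge("b", "q", "c")
        fg.graph.get_or_create_hub("1:1:A>T", "variant")
        return fg, e1, e2

    def test_single_edge_equality(self):
        fg, e1, e2 = self._fg_two_edges()
        out = node_contributions({e1: 0.3, e2: 0.0}, fg)
        assert out["a"] == 0.3 and out["b"] == 0.3

    def test_max_magnitude_rule(self):
        fg, e1, e2 = self._fg_two_edges()
        out = node_contributions({e1: 0.3, e2: -0.5}, fg)
        assert out["b"] == -0.5

    def test_isolated_node_zero(self):
        fg, e1, e2 = self._fg_two_edges()
        out = node_contributions({e1: 0.1, e2: 0.2}, fg)
        assert out["iso"] == 0.0

    def test_sum_and_mean_aggregations(self):
        fg, e1, e2 = self._fg_two_edges()
        assert node_contributions({e1: 0.3, e2: -0.5}, fg, "sum")["b"] == pytest.approx(-0.2)
        assert node_contributions({e1: 0.3, e2: -0.5}, fg, "mean")["b"] == pytest.approx(-0.1)
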