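"""GCN encoder, cosine scoring, masking splits, and rank evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import rankdata

from sdohkg.kg import Triplet
from sdohkg.linkpred import (EmbeddingTable, GCNConfig, ScoreError,
                             TrainingError, evaluate_split, exploratory_rank,
                             gcn_encode, initialize_features, node_order,
                             normalized_adjacency, random_mask_split,
                             score_pair, targeted_mask_split,
                             train_link_model)

from conftest import make_kg


class TestInitializeFeatures:
    def test_deterministic(self):
        kg = make_kg([("a", "r", "b")])
        x1 = initialize_features(kg, 8, seed=3)
        x2 = initialize_features(kg, 8, seed=3)
        assert np.array_equal(x1, x2)

    def test_different_seeds_differ(self):
        kg = make_kg([("a", "r", "b")])
        assert not np.array_equal(initialize_features(kg, 8, 0),
                                  initialize_features(kg, 8, 1))

    def test_zero_mean_and_scaled_variance(self):
        kg = make_kg([(f"n{i}", "r", f"n{i+1}") for i in range(999)])
        x = initialize_features(kg, 50, seed=0)
        se = (1 / math.sqrt(50)) / math.sqrt(x.size)
        assert abs(x.mean()) < 3 * se


class TestEncoder:
    def test_single_node_identity(self):
        kg = make_kg([])
        kg.add_node("only", "gene")
        a_hat = normalized_adjacency(kg)
        x = np.array([[1.0, -2.0, 3.0]])
        out = gcn_encode(a_hat, x, [np.eye(3)])
        assert np.allclose(out, x)

    def test_symmetry_for_identical_inputs(self):
        kg = make_kg([("a", "r", "b")])
        a_hat = normalized_adjacency(kg)
        x = np.array([[1.0, 2.0], [1.0, 2.0]])
        w = np.array([[0.5, -1.0], [2.0, 0.3]])
        out = gcn_encode(a_hat, x, [w, w])
        assert np.allclose(out[0], out[1])

    def test_path_graph_matches_dense_oracle(self):
        """One layer on a 4-node path equals hand-computed dense arithmetic."""
        kg = make_kg([("a", "r", "b"), ("b", "r", "c"), ("c", "r", "d")])
        order = node_order(kg)
        assert order == ["a", "b", "c", "d"]
        adj = np.array([[1, 1, 0, 0],
                        [1, 1, 1, 0],
                        [0, 1, 1, 1],
                        [0, 0, 1, 1]], dtype=float)  # A + I
        deg = adj.sum(axis=1)
        a_hat_dense = adj / np.sqrt(np.outer(deg, deg))
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 3))
        w = rng.normal(size=(3, 3))
        expected = a_hat_dense @ x @ w
        out = gcn_encode(normalized_adjacency(kg), x, [w])
        assert np.allclose(out, expected, atol=1e-12)

    def test_isolated_node_receives_self_message_only(self):
        kg = make_kg([("a", "r", "b")])
        kg.add_node("island", "gene")
        a_hat = normalized_adjacency(kg)
        x = np.array([[1.0], [2.0], [5.0]])  # order: a, b, island
        out = gcn_encode(a_hat, x, [np.eye(1)])
        assert out[node_order(kg).index("island"), 0] == pytest.approx(5.0)


class TestScorePair:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert score_pair(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert score_pair(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_hand_computed(self):
        got = score_pair(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        assert got == pytest.approx(1 / math.sqrt(2))

    def test_zero_vector_errors(self):
        with pytest.raises(ScoreError):
            score_pair(np.zeros(3), np.ones(3))

    @given(hnp.arrays(np.float64, 5, elements=st.floats(-10, 10)),
           hnp.arrays(np.float64, 5, elements=st.floats(-10, 10)))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, u, v):
        if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
            return
        s1, s2 = score_pair(u, v), score_pair(v, u)
        assert abs(s1 - s2) < 1e-12
        assert -1 - 1e-12 <= s1 <= 1 + 1e-12


def two_clique_graph():
    edges = []
    for block in (0, 1):
        members = [f"g{block}{i}" for i in range(6)]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                edges.append((a, "pp", b))
    return make_kg(edges, {f"g{b}{i}": "gene" for b in (0, 1) for i in range(6)})


def two_block_graph(n_per_block=25, seed=0):
    """50 genes in two latent blocks; dense within, sparse across."""
    rng = np.random.default_rng(seed)
    names = [f"g{b}{i:02d}" for b in (0, 1) for i in range(n_per_block)]
    types = {n: "gene" for n in names}
    edges = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p = 0.25 if a[1] == b[1] else 0.02
            if rng.random() < p:
                edges.append((a, "pp", b))
    kg = make_kg(edges, types)
    for n, t in types.items():
        kg.add_node(n, t)
    return kg


class TestTraining:
    def test_loss_decreases_on_small_fixture(self):
        kg = two_block_graph()
        emb = train_link_model(kg, GCNConfig(feature_dim=16, epochs=120, seed=0))
        losses = np.array(emb.loss_curve)
        assert len(losses) == 120
        # negatives are resampled each epoch, so individual epochs fluctuate;
        # the averaged trend must still fall from start to finish
        assert losses[-15:].mean() < losses[:15].mean()

    def test_planted_cliques_separate(self):
        kg = two_clique_graph()
        emb = train_link_model(kg, GCNConfig(feature_dim=16, epochs=200, seed=1))
        a = [emb.vector(f"g0{i}") for i in range(6)]
        b = [emb.vector(f"g1{i}") for i in range(6)]
        within = np.mean([score_pair(u, v) for i, u in enumerate(a)
                          for v in a[i + 1:]] +
                         [score_pair(u, v) for i, u in enumerate(b)
                          for v in b[i + 1:]])
        across = np.mean([score_pair(u, v) for u in a for v in b])
        assert within > across

    def test_zero_epochs_equals_initial_encoding(self):
        kg = two_clique_graph()
        dim = 8
        config = GCNConfig(feature_dim=dim, epochs=0, seed=5)
        emb = train_link_model(kg, config)
        # reconstruct the initial parameters exactly as training does
        rng = np.random.default_rng(config.seed)
        weights = [
            rng.normal(0.0, math.sqrt(2.0 / (dim + dim)),
                       size=(dim, dim)).astype(np.float32)
            for _ in range(config.n_layers)
        ]
        x = initialize_features(kg, dim, config.seed).astype(np.float32)
        a_hat = normalized_adjacency(kg).astype(np.float32)
        expected = gcn_encode(a_hat, x, weights).astype(np.float64)
        assert np.allclose(emb.matrix, expected)

    def test_deterministic_given_seed(self):
        kg = two_clique_graph()
        e1 = train_link_model(kg, GCNConfig(feature_dim=8, epochs=30, seed=2))
        e2 = train_link_model(kg, GCNConfig(feature_dim=8, epochs=30, seed=2))
        assert np.array_equal(e1.matrix, e2.matrix)

    def test_empty_graph_errors(self):
        from sdohkg.kg import KnowledgeGraph
        with pytest.raises(TrainingError):
            train_link_model(KnowledgeGraph(), GCNConfig())


class TestRandomMaskSplit:
    def _kg(self):
        edges = [(f"d{i}", "disease_gene", f"g{i % 20}") for i in range(100)]
        types = {f"d{i}": "disease" for i in range(100)}
        types.update({f"g{i}": "gene" for i in range(20)})
        return make_kg(edges, types)

    def test_exact_counts(self):
        kg = self._kg()
        split = random_mask_split(kg, "disease_gene", 0.2, seed=0)
        assert len(split.positives) == 20
        assert len(split.training_graph.edges_of_relation("disease_gene")) == 80

    def test_zero_mask_errors(self):
        kg = make_kg([("a", "r", "b"), ("c", "r", "d")])
        with pytest.raises(ValueError, match="zero"):
            random_mask_split(kg, "r", 0.2, seed=0)

    def test_absent_relation_errors(self):
        with pytest.raises(ValueError, match="absent"):
            random_mask_split(self._kg(), "nope", 0.2, seed=0)

    def test_same_seed_same_split(self):
        kg = self._kg()
        s1 = random_mask_split(kg, "disease_gene", 0.2, seed=7)
        s2 = random_mask_split(kg, "disease_gene", 0.2, seed=7)
        assert [p.key for p in s1.positives] == [p.key for p in s2.positives]

    def test_other_relations_untouched(self):
        kg = self._kg()
        kg.add_edge(Triplet("d0", "disease_drug", "x", "disease", "drug"))
        split = random_mask_split(kg, "disease_gene", 0.2, seed=0)
        assert len(split.training_graph.edges_of_relation("disease_drug")) == 1


class TestTargetedMaskSplit:
    def _kg(self):
        genes = {f"g{i}": "gene" for i in range(10)}
        edges = [("g0", "pp", f"g{i}") for i in range(1, 8)]
        return make_kg(edges, genes)

    def test_partner_edges_held_out(self):
        split = targeted_mask_split(self._kg(), "g0",
                                    ["g1", "g2", "g3", "g4", "g5"])
        assert len(split.positives) == 5
        assert len(split.training_graph.edges) == 2

    def test_disjoint_partner_list_errors(self):
        with pytest.raises(ValueError, match="empty evaluation"):
            targeted_mask_split(self._kg(), "g0", ["g8", "g9"])

    def test_self_partner_ignored(self):
        split = targeted_mask_split(self._kg(), "g0", ["g0", "g1"])
        assert len(split.positives) == 1

    def test_missing_gene_errors(self):
        with pytest.raises(ValueError, match="not in graph"):
            targeted_mask_split(self._kg(), "nope", ["g1"])


def brute_force_reciprocal_ranks(split, embeddings, n_negatives, seed):
    """Independent oracle: explicitly score, sort, and mid-rank every
    candidate list using the same sampled negatives."""
    rng = np.random.default_rng(seed)
    kg = split.full_graph
    keys = kg.edge_keys()
    out = []
    for pos in split.positives:
        tail_type = kg.node_types[pos.tail]
        candidates = [x for x in kg.nodes_of_type(tail_type)
                      if x != pos.tail and x != pos.head
                      and (pos.head, pos.relation, x) not in keys]
        chosen = rng.choice(len(candidates), size=n_negatives, replace=False)
        tails = [pos.tail] + [candidates[j] for j in chosen]
        scores = np.array([
            float(np.dot(embeddings.vector(pos.head), embeddings.vector(t))
                  / (np.linalg.norm(embeddings.vector(pos.head))
                     * np.linalg.norm(embeddings.vector(t))))
            for t in tails
        ])
        # explicit sort-based mid-rank of the positive (index 0)
        desc = np.argsort(-scores, kind="stable")
        positions = np.empty(len(scores))
        positions[desc] = np.arange(1, len(scores) + 1)
        tied = scores == scores[0]
        rank = positions[tied].mean()
        out.append(1.0 / rank)
    return np.array(out)


class TestEvaluateSplit:
    def _setup(self, n_genes=30, dim=6, seed=0):
        rng = np.random.default_rng(seed)
        types = {f"d{i}": "disease" for i in range(10)}
        types.update({f"g{i}": "gene" for i in range(n_genes)})
        edges = [(f"d{i}", "disease_gene", f"g{i}") for i in range(10)]
        kg = make_kg(edges, types)
        for nid, ntype in types.items():
            kg.add_node(nid, ntype)  # genes beyond g9 are candidate negatives
        split = random_mask_split(kg, "disease_gene", 0.5, seed=seed)
        emb = EmbeddingTable(node_ids=node_order(kg),
                             matrix=rng.normal(size=(kg.n_nodes, dim)))
        return kg, split, emb

    def test_matches_bruteforce_oracle(self):
        _, split, emb = self._setup()
        got = evaluate_split(split, emb, eval_negatives_per_positive=20, seed=3)
        want = brute_force_reciprocal_ranks(split, emb, 20, seed=3)
        assert np.allclose(got, want, atol=0, rtol=0)

    def test_perfect_positive_gets_rr_one(self):
        kg, split, emb = self._setup()
        # make every positive's tail embedding identical to its head's
        m = emb.matrix.copy()
        for pos in split.positives:
            m[emb.index_of(pos.tail)] = m[emb.index_of(pos.head)]
        emb2 = EmbeddingTable(node_ids=emb.node_ids, matrix=m)
        rr = evaluate_split(split, emb2, 20, seed=0)
        assert np.all(rr == 1.0)

    def test_tie_gets_mid_rank(self):
        kg, split, emb = self._setup()
        m = np.tile(np.arange(1.0, 7.0), (emb.matrix.shape[0], 1))
        # all vectors identical -> every candidate ties -> rank = (n+1)/2
        emb2 = EmbeddingTable(node_ids=emb.node_ids, matrix=m)
        rr = evaluate_split(split, emb2, 20, seed=0)
        assert np.allclose(rr, 1.0 / 11.0)  # 21 candidates, mid-rank 11

    def test_insufficient_negatives_error(self):
        _, split, emb = self._setup(n_genes=5)
        with pytest.raises(ValueError, match="candidate negatives"):
            evaluate_split(split, emb, eval_negatives_per_positive=50, seed=0)

    def test_rank_second_of_four(self):
        types = {"d0": "disease"}
        types.update({f"g{i}": "gene" for i in range(6)})
        kg = make_kg([("d0", "disease_gene", "g0"),
                      ("d0", "disease_gene", "g5")], types)
        for nid, ntype in types.items():
            kg.add_node(nid, ntype)
        split = random_mask_split(kg, "disease_gene", 0.5, seed=1)
        pos = split.positives[0]
        vecs = {n: np.array([0.0, 1.0]) for n in node_order(kg)}  # cosine 0
        vecs[pos.head] = np.array([1.0, 0.0])
        vecs[pos.tail] = np.array([1.0, 0.5])   # cosine ~0.894, rank 2
        best = [g for g in types if types[g] == "gene"
                and g not in (pos.tail, pos.head)
                and not kg.has_edge(pos.head, pos.relation, g)][0]
        vecs[best] = np.array([1.0, 0.1])       # cosine ~0.995, rank 1
        emb = EmbeddingTable(node_ids=node_order(kg),
                             matrix=np.stack([vecs[n] for n in node_order(kg)]))
        rr = evaluate_split(split, emb, 4, seed=2)  # all four candidates
        assert rr[0] == pytest.approx(0.5)


class TestExploratoryRank:
    def _fixture(self):
        types = {f"s{i}": "sdoh" for i in range(2)}
        types.update({f"g{i}": "gene" for i in range(6)})
        kg = make_kg([("s0", "sdoh_gene", "g0"), ("s1", "sdoh_gene", "g1")],
                     types)
        for nid, ntype in types.items():
            kg.add_node(nid, ntype)
        rng = np.random.default_rng(0)
        emb = EmbeddingTable(node_ids=node_order(kg),
                             matrix=rng.normal(size=(kg.n_nodes, 4)))
        return kg, emb

    def test_top_fraction_count_and_order(self):
        kg, emb = self._fixture()
        out = exploratory_rank(kg, emb, "sdoh", "gene", top_fraction=0.2)
        assert len(out) == 2  # ceil(0.2 * 10 non-edges)
        assert (out["score"].diff().dropna() <= 1e-12).all()

    def test_full_fraction_returns_all_nonedges(self):
        kg, emb = self._fixture()
        out = exploratory_rank(kg, emb, "sdoh", "gene", top_fraction=1.0)
        assert len(out) == 2 * 6 - 2  # all pairs minus the 2 existing edges
        existing = {("s0", "g0"), ("s1", "g1")}
        assert existing.isdisjoint(set(zip(out["head"], out["tail"])))

    def test_no_candidates_errors(self):
        types = {"s0": "sdoh", "g0": "gene"}
        kg = make_kg([("s0", "sdoh_gene", "g0")], types)
        emb = EmbeddingTable(node_ids=node_order(kg),
                             matrix=np.ones((2, 3)))
        with pytest.raises(ValueError, match="no candidate"):
            exploratory_rank(kg, emb, "sdoh", "gene", top_fraction=1.0)
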