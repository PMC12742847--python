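"""Generators: planted structure, determinism, configuration validation."""

import json

import numpy as np
import pytest

from sdohkg.synthetic import (ConfigurationError, CorpusConfig, GroundTruth,
                              KGConfig, OmicsSimConfig, PatientSimConfig,
                              generate_bio_kg, generate_corpus,
                              generate_omics, generate_patient_table)


def corpus_as_json(docs):
    return json.dumps([
        [d.doc_id, d.sentences, [tuple(m.__dict__.values()) for m in d.mentions]]
        for d in docs
    ])


class TestCorpus:
    def test_empty(self):
        docs, truth = generate_corpus(CorpusConfig(n_docs=0))
        assert docs == [] and truth.linked_pairs == []

    def test_invalid_probabilities(self):
        with pytest.raises(ConfigurationError):
            generate_corpus(CorpusConfig(p_link=0.2, p_background=0.5))

    def test_empty_inventory_errors(self):
        with pytest.raises(ConfigurationError):
            generate_corpus(CorpusConfig(n_docs=5, bio_entity_inventory=[],
                                         linked_pairs=[]))

    def test_unknown_linked_pair_errors(self):
        with pytest.raises(ConfigurationError):
            generate_corpus(CorpusConfig(linked_pairs=[("nope", "also nope")]))

    def test_deterministic_given_seed(self):
        a, _ = generate_corpus(CorpusConfig(n_docs=30, seed=3))
        b, _ = generate_corpus(CorpusConfig(n_docs=30, seed=3))
        c, _ = generate_corpus(CorpusConfig(n_docs=30, seed=4))
        assert corpus_as_json(a) == corpus_as_json(b)
        assert corpus_as_json(a) != corpus_as_json(c)

    def test_comention_rate_matches_p_link(self):
        """Single linked pair: the fraction of sentences carrying both
        entities should sit within 3 binomial SE of p_link."""
        p = 0.8
        config = CorpusConfig(
            n_docs=100, sentences_per_doc=(5, 5),
            bio_entity_inventory=[("g", "gene")],
            sdoh_entity_inventory=[("s", "Economic Stability", "income")],
            linked_pairs=[("g", "s")],
            p_link=p, p_background=0.0, seed=11,
        )
        docs, _ = generate_corpus(config)
        n_sent = sum(len(d.sentences) for d in docs)
        assert n_sent == 500
        n_both = sum(
            1 for d in docs for s in range(len(d.sentences))
            if {m.entity_id for m in d.mentions if m.sentence_index == s}
            == {"g", "s"}
        )
        se = np.sqrt(p * (1 - p) / n_sent)
        assert abs(n_both / n_sent - p) < 3 * se

    def test_mentions_located_in_sentences(self):
        docs, _ = generate_corpus(CorpusConfig(n_docs=10, seed=0))
        for d in docs:
            d.validate()  # surface occurs in its sentence


class TestBioKG:
    SMALL_COUNTS = {"gene": 60, "disease": 40, "drug": 30,
                    "effect_phenotype": 20, "anatomy": 20,
                    "biological_process": 20, "sdoh": 10}

    def test_too_many_blocks_errors(self):
        with pytest.raises(ConfigurationError):
            generate_bio_kg(KGConfig(node_counts=dict(self.SMALL_COUNTS),
                                     n_blocks=25))

    def test_equal_probabilities_make_blocks_invisible(self):
        """With p_within = p_between the within/between edge densities agree
        to within 3 SE of the two-proportion comparison."""
        kg, truth = generate_bio_kg(KGConfig(
            node_counts={**self.SMALL_COUNTS, "gene": 200, "disease": 150},
            p_within=0.05, p_between=0.05, n_blocks=2, seed=5))
        blocks = truth.block_assignments
        genes = kg.nodes_of_type("gene")
        diseases = kg.nodes_of_type("disease")
        edges = {(e.head, e.tail) for e in kg.edges_of_relation("disease_gene")}
        n_within = n_between = within_pairs = between_pairs = 0
        for d in diseases:
            for g in genes:
                if blocks[d] == blocks[g]:
                    within_pairs += 1
                    n_within += (d, g) in edges
                else:
                    between_pairs += 1
                    n_between += (d, g) in edges
        p_w = n_within / within_pairs
        p_b = n_between / between_pairs
        pooled = (n_within + n_between) / (within_pairs + between_pairs)
        se = np.sqrt(pooled * (1 - pooled)
                     * (1 / within_pairs + 1 / between_pairs))
        assert abs(p_w - p_b) < 3 * se

    def test_zero_between_blocks_never_crossed(self):
        kg, truth = generate_bio_kg(KGConfig(
            node_counts=dict(self.SMALL_COUNTS), n_blocks=2,
            p_within=0.3, p_between=0.0, seed=1))
        blocks = truth.block_assignments
        crossing = [
            e for e in kg.edges_of_relation("disease_gene")
            if blocks[e.head] != blocks[e.tail]
        ]
        assert crossing == []

    def test_complete_bipartite_counts(self):
        """p = 1 in a single block gives exactly |H| x |T| edges per relation."""
        counts = {"gene": 7, "disease": 5, "drug": 4, "effect_phenotype": 3,
                  "anatomy": 3, "biological_process": 3, "sdoh": 0}
        kg, _ = generate_bio_kg(KGConfig(
            node_counts=counts, n_blocks=1, p_within=1.0, p_between=1.0,
            seed=0))
        assert len(kg.edges_of_relation("disease_gene")) == 5 * 7
        assert len(kg.edges_of_relation("drug_effect")) == 4 * 3
        assert len(kg.edges_of_relation("gene_anatomy")) == 7 * 3

    def test_informative_sdoh_edges_stay_within_block(self):
        kg, truth = generate_bio_kg(KGConfig(
            node_counts=dict(self.SMALL_COUNTS), n_blocks=2,
            aux_informative=True, seed=2))
        blocks = truth.block_assignments
        for rel in ("sdoh_gene", "sdoh_disease"):
            for e in kg.edges_of_relation(rel):
                assert blocks[e.head] == blocks[e.tail]

    def test_deterministic_given_seed(self):
        a, _ = generate_bio_kg(KGConfig(node_counts=dict(self.SMALL_COUNTS), seed=9))
        b, _ = generate_bio_kg(KGConfig(node_counts=dict(self.SMALL_COUNTS), seed=9))
        assert a == b


class TestPatients:
    def test_empty(self):
        records, _ = generate_patient_table(PatientSimConfig(n_patients=0))
        assert records == []

    def test_empty_icd_inventory_errors(self):
        with pytest.raises(ConfigurationError):
            generate_patient_table(PatientSimConfig(
                n_patients=5, icd_inventory=[], target_codes=[]))

    def test_records_carry_required_fields(self):
        records, _ = generate_patient_table(PatientSimConfig(n_patients=30, seed=1))
        for r in records:
            assert len(r.demographics) == 6
            assert len(r.diagnoses) >= 1
        # note text embeds the SDoH terms the generator assigned
        assert any("social history notable for" in r.note_text for r in records)

    def test_certain_rule_forces_pair_in_all_patients(self):
        config = PatientSimConfig(
            n_patients=25,
            co_assignment_rules=[(("sdoh", "food insecurity"), ("icd", "3310"), 1.0)],
            seed=2)
        records, _ = generate_patient_table(config)
        n_pair = sum(1 for r in records
                     if "3310" in r.diagnoses and "food insecurity" in r.note_text)
        assert n_pair == 25

    def test_rule_rate_within_binomial_error(self):
        rate, n = 0.4, 200
        config = PatientSimConfig(
            n_patients=n,
            sdoh_term_inventory=["lives alone"],
            co_assignment_rules=[(("sdoh", "lives alone"), ("icd", "2900"), rate)],
            seed=3)
        records, _ = generate_patient_table(config)
        n_pair = sum(1 for r in records
                     if "2900" in r.diagnoses and "lives alone" in r.note_text)
        se = np.sqrt(n * rate * (1 - rate))
        # terms can also co-occur by chance, so the planted count is a floor
        assert n_pair >= rate * n - 3 * se

    def test_deterministic(self):
        a, _ = generate_patient_table(PatientSimConfig(n_patients=20, seed=5))
        b, _ = generate_patient_table(PatientSimConfig(n_patients=20, seed=5))
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]


class TestOmics:
    def test_bad_noise_sd(self):
        with pytest.raises(ConfigurationError):
            generate_omics(OmicsSimConfig(noise_sd=0.0))

    def test_shapes_and_labels(self):
        m, g, cov, truth = generate_omics(OmicsSimConfig(
            n_case=10, n_control=12, n_features=30, seed=0))
        assert m.shape == (22, 30)
        assert (g == "case").sum() == 10
        assert set(cov.columns) == {"age", "sex"}
        assert set(truth.planted_de_set) <= set(m.columns)

    def test_planted_effect_visible_in_group_means(self):
        config = OmicsSimConfig(n_case=200, n_control=200, n_features=4,
                                planted_de_set=[0], effect_size=3.0, seed=1)
        m, g, _, truth = generate_omics(config)
        feat = truth.planted_de_set[0]
        diff = m.loc[g == "case", feat].mean() - m.loc[g == "control", feat].mean()
        # 3 SE of a two-sample mean difference with unit noise
        assert abs(diff - 3.0) < 3 * np.sqrt(2 / 200)

    def test_deterministic(self):
        a = generate_omics(OmicsSimConfig(seed=4))[0]
        b = generate_omics(OmicsSimConfig(seed=4))[0]
        assert a.equals(b)


def test_ground_truth_roundtrip():
    gt = GroundTruth(
        linked_pairs=[("a", "b")],
        block_assignments={"x": 0, "y": 1},
        planted_de_set=["F1"],
        effect_sizes={"F1": 2.5},
        co_assignment_rules=[{"a": ["sdoh", "t"], "b": ["icd", "c"], "rate": 0.4}],
    )
    assert GroundTruth.from_json(gt.to_json()) == gt
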