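"""Synthetic-data generators with known ground truth.

The production pipeline consumes restricted or very large inputs (credentialed
EHR tables, a PubMed crawl, a full biological knowledge graph, post-mortem
proteomics).  This module generates structurally faithful stand-ins for each
of them — abstracts with planted entity co-occurrence, patient tables with
demographics/diagnoses/drugs and SDoH terms embedded in note text, a typed
biological KG with latent block (community) structure, and omics matrices with
planted group effects — so every downstream stage can be tested against known
ground truth.

All generators draw from a single :class:`numpy.random.Generator` stream
seeded by the config, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .kg import KnowledgeGraph, Triplet
from .textmine import Document, Mention

#: The seven evaluated relation classes: relation label -> (head type, tail type).
RELATION_CLASSES: dict[str, tuple[str, str]] = {
    "disease_gene": ("disease", "gene"),
    "disease_drug": ("disease", "drug"),
    "disease_effect": ("disease", "effect_phenotype"),
    "gene_anatomy": ("gene", "anatomy"),
    "drug_effect": ("drug", "effect_phenotype"),
    "gene_bioprocess": ("gene", "biological_process"),
    "drug_gene": ("drug", "gene"),
}

#: Relations attaching SDoH nodes to the biological graph.
SDOH_RELATIONS: dict[str, tuple[str, str]] = {
    "sdoh_disease": ("sdoh", "disease"),
    "sdoh_gene": ("sdoh", "gene"),
}


class ConfigurationError(ValueError):
    pass


@dataclass
class GroundTruth:
    """What the generator planted; the oracle for downstream recovery tests."""

    linked_pairs: list[tuple[str, str]] = field(default_factory=list)
    block_assignments: dict[str, int] = field(default_factory=dict)
    planted_de_set: list[str] = field(default_factory=list)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    co_assignment_rules: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["linked_pairs"] = [list(p) for p in self.linked_pairs]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            linked_pairs=[tuple(p) for p in d.get("linked_pairs", [])],
            block_assignments=d.get("block_assignments", {}),
            planted_de_set=d.get("planted_de_set", []),
            effect_sizes=d.get("effect_sizes", {}),
            co_assignment_rules=d.get("co_assignment_rules", []),
        )


# ---------------------------------------------------------------------------
# literature corpus
# ---------------------------------------------------------------------------

@dataclass
class CorpusConfig:
    """Corpus with planted sentence-level co-occurrence structure.

    Each sentence is a bag of entity mentions: a seed entity is drawn
    uniformly; if the seed belongs to a linked pair, its partner joins the
    sentence with probability ``p_link``; an unrelated entity of the opposite
    kind joins with probability ``p_background``.
    """

    n_docs: int = 200
    sentences_per_doc: tuple[int, int] = (4, 10)
    bio_entity_inventory: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("apoe", "gene"), ("trem2", "gene"), ("bin1", "gene"),
            ("alzheimer disease", "disease"), ("hypertension", "disease"),
            ("donepezil", "drug"), ("memantine", "drug"),
        ]
    )
    sdoh_entity_inventory: list[tuple[str, str, str]] = field(
        default_factory=lambda: [
            ("food insecurity", "Economic Stability", "food access"),
            ("low education", "Education Access and Quality", "educational attainment"),
            ("social isolation", "Social and Community Context", "social support"),
            ("housing instability", "Economic Stability", "housing"),
            ("air pollution", "Neighborhood and Built Environment", "environmental exposure"),
        ]
    )
    linked_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("apoe", "low education"),
            ("alzheimer disease", "social isolation"),
            ("hypertension", "food insecurity"),
        ]
    )
    p_link: float = 0.8
    p_background: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs < 0:
            raise ConfigurationError("n_docs must be >= 0")
        if self.n_docs > 0 and (
            not self.bio_entity_inventory or not self.sdoh_entity_inventory
        ):
            raise ConfigurationError("entity inventories must be non-empty")
        if not (0.0 <= self.p_background < self.p_link <= 1.0):
            raise ConfigurationError(
                "need 0 <= p_background < p_link <= 1, got "
                f"p_background={self.p_background}, p_link={self.p_link}"
            )
        lo, hi = self.sentences_per_doc
        if not (1 <= lo <= hi):
            raise ConfigurationError("sentences_per_doc must be a 1-based range")
        names = {n for n, _ in self.bio_entity_inventory} | {
            n for n, _, _ in self.sdoh_entity_inventory
        }
        for a, b in self.linked_pairs:
            if a not in names or b not in names:
                raise ConfigurationError(
                    f"linked pair ({a!r}, {b!r}) references unknown entities"
                )


def generate_corpus(config: CorpusConfig) -> tuple[list[Document], GroundTruth]:
    """Generate abstracts with planted co-occurrence; see :class:`CorpusConfig`."""
    config.validate()
    gt = GroundTruth(linked_pairs=list(config.linked_pairs))
    if config.n_docs == 0:
        return [], GroundTruth()
    rng = np.random.default_rng(config.seed)

    bio_type = {n: t for n, t in config.bio_entity_inventory}
    sdoh_names = [n for n, _, _ in config.sdoh_entity_inventory]
    all_names = sorted(bio_type) + sorted(sdoh_names)
    kind = {n: ("bio" if n in bio_type else "sdoh") for n in all_names}
    partners: dict[str, list[str]] = {}
    for a, b in config.linked_pairs:
        partners.setdefault(a, []).append(b)
        partners.setdefault(b, []).append(a)
    linked_to: dict[str, set[str]] = {n: set(partners.get(n, ())) for n in all_names}

    def etype(name: str) -> str:
        return bio_type.get(name, "sdoh")

    docs: list[Document] = []
    lo, hi = config.sentences_per_doc
    for d in range(config.n_docs):
        n_sent = int(rng.integers(lo, hi + 1))
        sentences: list[str] = []
        mentions: list[Mention] = []
        for s in range(n_sent):
            seed_name = all_names[int(rng.integers(len(all_names)))]
            members = [seed_name]
            ps = partners.get(seed_name)
            if ps and rng.random() < config.p_link:
                members.append(ps[int(rng.integers(len(ps)))])
            if config.p_background > 0 and rng.random() < config.p_background:
                opposite = [
                    n for n in all_names
                    if kind[n] != kind[seed_name] and n not in linked_to[seed_name]
                ]
                if opposite:
                    cand = opposite[int(rng.integers(len(opposite)))]
                    if cand not in members:
                        members.append(cand)
            sentences.append("this study examines " + " and ".join(members))
            for name in members:
                mentions.append(Mention(s, name, name, etype(name)))
        doc = Document(doc_id=f"doc{d:05d}", sentences=sentences, mentions=mentions)
        doc.validate()
        docs.append(doc)
    return docs, gt


# ---------------------------------------------------------------------------
# biological knowledge graph
# ---------------------------------------------------------------------------

@dataclass
class KGConfig:
    """Typed KG with latent block structure over seven relation classes.

    Every node gets a latent block; within each relation class an edge is
    drawn with probability ``p_within`` when endpoints share a block and
    ``p_between`` otherwise.  SDoH nodes attach to disease and gene nodes:
    when ``aux_informative`` they connect within their own block with
    probability ``p_sdoh`` (carrying community signal), otherwise uniformly at
    a degree-matched rate ``p_sdoh / n_blocks`` (pure noise control).
    """

    node_counts: dict[str, int] = field(
        default_factory=lambda: {
            "gene": 600, "disease": 300, "drug": 300,
            "effect_phenotype": 250, "anatomy": 150,
            "biological_process": 250, "sdoh": 50,
        }
    )
    n_blocks: int = 8
    p_within: float = 0.03
    p_between: float = 0.003
    p_sdoh: float = 0.12
    relation_classes: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(RELATION_CLASSES)
    )
    aux_informative: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ConfigurationError(
                "need 0 <= p_between <= p_within <= 1, got "
                f"p_between={self.p_between}, p_within={self.p_within}"
            )
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        required = {t for pair in self.relation_classes.values() for t in pair}
        for t in sorted(required):
            count = self.node_counts.get(t, 0)
            if count < self.n_blocks:
                raise ConfigurationError(
                    f"n_blocks={self.n_blocks} exceeds node count {count} of "
                    f"required type {t!r}"
                )


def generate_bio_kg(config: KGConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate a typed KG with latent blocks; see :class:`KGConfig`."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    kg = KnowledgeGraph()

    node_ids: dict[str, list[str]] = {}
    blocks: dict[str, np.ndarray] = {}
    assignment: dict[str, int] = {}
    for ntype in sorted(config.node_counts):
        count = config.node_counts[ntype]
        ids = [f"{ntype}_{i:04d}" for i in range(count)]
        node_ids[ntype] = ids
        b = np.arange(count) % config.n_blocks
        blocks[ntype] = b
        for nid, blk in zip(ids, b):
            kg.add_node(nid, ntype)
            assignment[nid] = int(blk)

    def draw_block_edges(relation: str, htype: str, ttype: str,
                         p_in: float, p_out: float) -> None:
        heads, tails = node_ids[htype], node_ids[ttype]
        hb = blocks[htype][:, None]
        tb = blocks[ttype][None, :]
        p = np.where(hb == tb, p_in, p_out)
        mask = rng.random((len(heads), len(tails))) < p
        if htype == ttype:
            np.fill_diagonal(mask, False)
        hi, ti = np.nonzero(mask)
        for i, j in zip(hi, ti):
            kg.add_edge(Triplet(heads[i], relation, tails[j],
                                head_type=htype, tail_type=ttype))

    for relation in sorted(config.relation_classes):
        htype, ttype = config.relation_classes[relation]
        draw_block_edges(relation, htype, ttype, config.p_within, config.p_between)

    if "sdoh" in config.node_counts and config.node_counts["sdoh"] > 0:
        for relation in sorted(SDOH_RELATIONS):
            _, ttype = SDOH_RELATIONS[relation]
            if ttype not in node_ids:
                continue
            if config.aux_informative:
                draw_block_edges(relation, "sdoh", ttype, config.p_sdoh, 0.0)
            else:
                p_uniform = config.p_sdoh / config.n_blocks
                draw_block_edges(relation, "sdoh", ttype, p_uniform, p_uniform)

    return kg, GroundTruth(block_assignments=assignment)


# ---------------------------------------------------------------------------
# patient tables
# ---------------------------------------------------------------------------

#: The six demographic attributes carried by every patient record.
DEMOGRAPHIC_ATTRIBUTES = (
    "age", "ethnicity", "religion", "marital_status", "gender", "insurance",
)

DEFAULT_DEMOGRAPHIC_VALUES: dict[str, list] = {
    "ethnicity": ["white", "black", "hispanic", "asian", "other"],
    "religion": ["catholic", "protestant", "jewish", "none", "other"],
    "marital_status": ["married", "single", "widowed", "divorced"],
    "gender": ["f", "m"],
    "insurance": ["medicare", "medicaid", "private", "self pay"],
}

#: ICD-9 codes identifying the AD/ADRD cohort.
DEFAULT_TARGET_ICD9 = (
    "3310", "2900", "2901", "2902", "2903", "2904",
    "3311", "3312", "33182", "2941", "4380",
)


@dataclass
class PatientSimConfig:
    """Patient tables with planted entity co-assignment.

    ``co_assignment_rules`` are ``(entity_a, entity_b, rate)`` with each
    entity a ``(kind, value)`` pair, kind in {"icd", "drug", "sdoh"}: with
    probability ``rate`` a patient receives both entities.
    """

    n_patients: int = 200
    demographic_values: dict[str, list] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_DEMOGRAPHIC_VALUES.items()}
    )
    age_range: tuple[int, int] = (55, 95)
    icd_inventory: list[str] = field(
        default_factory=lambda: list(DEFAULT_TARGET_ICD9) + ["4019", "25000", "2859", "5849"]
    )
    target_codes: list[str] = field(default_factory=lambda: list(DEFAULT_TARGET_ICD9))
    drug_inventory: list[str] = field(
        default_factory=lambda: ["donepezil", "memantine", "aspirin", "lisinopril", "metformin"]
    )
    sdoh_term_inventory: list[str] = field(
        default_factory=lambda: [
            "lives alone", "food insecurity", "homelessness",
            "social isolation", "low income",
        ]
    )
    co_assignment_rules: list[tuple[tuple[str, str], tuple[str, str], float]] = field(
        default_factory=lambda: [
            (("sdoh", "lives alone"), ("icd", "3310"), 0.4),
        ]
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.n_patients > 0 and not self.icd_inventory:
            raise ConfigurationError("icd_inventory must be non-empty")
        if not set(self.target_codes) <= set(self.icd_inventory):
            raise ConfigurationError("target_codes must be a subset of icd_inventory")
        for a, b, rate in self.co_assignment_rules:
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"rule rate {rate} outside [0, 1]")
            for kind, value in (a, b):
                if kind not in ("icd", "drug", "sdoh"):
                    raise ConfigurationError(f"unknown rule entity kind {kind!r}")


def generate_patient_table(config: PatientSimConfig):
    """Generate patient records; returns (records, ground truth).

    Every record carries all six demographic attributes, at least one
    diagnosis code, and note text embedding its SDoH terms.
    """
    from .ehr import PatientRecord  # local import to avoid a module cycle

    config.validate()
    gt = GroundTruth(
        co_assignment_rules=[
            {"a": list(a), "b": list(b), "rate": rate}
            for a, b, rate in config.co_assignment_rules
        ]
    )
    if config.n_patients == 0:
        return [], gt
    rng = np.random.default_rng(config.seed)

    records = []
    for i in range(config.n_patients):
        demo = {"age": int(rng.integers(config.age_range[0], config.age_range[1] + 1))}
        for attr in DEMOGRAPHIC_ATTRIBUTES[1:]:
            values = config.demographic_values.get(attr) or ["unknown"]
            demo[attr] = values[int(rng.integers(len(values)))]

        n_dx = int(rng.integers(1, 4))
        idx = rng.choice(len(config.icd_inventory), size=n_dx, replace=False)
        diagnoses = [config.icd_inventory[j] for j in sorted(idx)]

        n_rx = int(rng.integers(0, 4))
        if n_rx:
            idx = rng.choice(len(config.drug_inventory), size=min(n_rx, len(config.drug_inventory)), replace=False)
            drugs = [config.drug_inventory[j] for j in sorted(idx)]
        else:
            drugs = []

        n_sdoh = int(rng.integers(0, 3))
        if n_sdoh:
            idx = rng.choice(len(config.sdoh_term_inventory), size=min(n_sdoh, len(config.sdoh_term_inventory)), replace=False)
            sdoh_terms = [config.sdoh_term_inventory[j] for j in sorted(idx)]
        else:
            sdoh_terms = []

        for a, b, rate in config.co_assignment_rules:
            if rng.random() < rate:
                for kind, value in (a, b):
                    target = {"icd": diagnoses, "drug": drugs, "sdoh": sdoh_terms}[kind]
                    if value not in target:
                        target.append(value)

        note_sentences = ["patient admitted for evaluation of cognitive decline."]
        note_sentences += [f"social history notable for {term}." for term in sdoh_terms]
        note_sentences.append("discharged in stable condition.")
        records.append(
            PatientRecord(
                subject_id=f"P{i:05d}",
                demographics=demo,
                diagnoses=diagnoses,
                drugs=drugs,
                note_text=" ".join(note_sentences),
            )
        )
    return records, gt


# ---------------------------------------------------------------------------
# omics matrices
# ---------------------------------------------------------------------------

@dataclass
class OmicsSimConfig:
    """Case/control omics matrix with planted group effects.

    ``value(s, f) = baseline(f) + effect(f) * group(s) + covariate terms +
    Normal(0, noise_sd)`` on a log scale.  Defaults emulate a post-mortem
    proteomics design: 50 cases / 50 controls, 1,000 features, 5% planted at
    3 x noise_sd, one continuous (age-like) and one binary (sex-like)
    covariate.
    """

    n_case: int = 50
    n_control: int = 50
    n_features: int = 1000
    planted_fraction: float = 0.05
    planted_de_set: list[int] | None = None
    effect_size: float = 3.0
    effect_sizes: dict[int, float] | None = None
    age_coef: float = 0.02
    sex_coef: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.n_case < 0 or self.n_control < 0 or self.n_features < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.planted_de_set is not None:
            if any(not 0 <= f < self.n_features for f in self.planted_de_set):
                raise ConfigurationError("planted_de_set indices out of range")
        elif not 0.0 <= self.planted_fraction <= 1.0:
            raise ConfigurationError("planted_fraction outside [0, 1]")


def generate_omics(config: OmicsSimConfig):
    """Generate (matrix, group labels, covariates, ground truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    features = [f"F{j:04d}" for j in range(config.n_features)]
    samples = [f"S{i:04d}" for i in range(n)]
    group = np.array([1] * config.n_case + [0] * config.n_control)

    if config.planted_de_set is not None:
        planted = sorted(config.planted_de_set)
    else:
        k = int(round(config.planted_fraction * config.n_features))
        planted = sorted(rng.choice(config.n_features, size=k, replace=False).tolist())

    effects = np.zeros(config.n_features)
    for j in planted:
        effects[j] = config.effect_size
    if config.effect_sizes:
        for j, e in config.effect_sizes.items():
            effects[j] = e

    age = rng.normal(80.0, 8.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    baseline = rng.normal(10.0, 1.0, size=config.n_features)

    values = (
        baseline[None, :]
        + np.outer(group, effects)
        + np.outer(age - age.mean(), np.full(config.n_features, config.age_coef))
        + np.outer(sex, np.full(config.n_features, config.sex_coef))
        + rng.normal(0.0, config.noise_sd, size=(n, config.n_features))
    )

    matrix = pd.DataFrame(values, index=samples, columns=features)
    labels = pd.Series(
        np.where(group == 1, "case", "control"), index=samples, name="group"
    )
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=samples)
    gt = GroundTruth(
        planted_de_set=[features[j] for j in planted],
        effect_sizes={features[j]: float(effects[j]) for j in planted},
    )
    return matrix, labels, covariates, gt
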