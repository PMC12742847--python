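"""Literature text mining: cleaning, entity recognition and SDoH
classification interfaces, sentence co-occurrence scoring, and triplet
extraction.

The production study runs external NER / LLM services over PubMed abstracts;
here those services sit behind small deterministic interfaces
(:class:`Recognizer`, :class:`Classifier`, :class:`RelationExtractor`) with
dictionary-backed reference implementations, so the mining pipeline itself is
fully testable offline.

The co-occurrence score between a biomedical entity and an SDoH entity is the
overlap coefficient at sentence level::

    score = n_both / max(n_a, n_b)

where ``n_both`` counts sentences mentioning both entities and ``n_a``,
``n_b`` count sentences mentioning each entity.  Pairs with score >= 0.5
(inclusive) are retained as knowledge triplets by default.
"""

from __future__ import annotations

import logging
import re
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .kg import Triplet

logger = logging.getLogger(__name__)

#: The five top-level SDoH categories (Healthy People 2030 scheme).
SDOH_CATEGORIES = (
    "Economic Stability",
    "Education Access and Quality",
    "Health Care Access and Quality",
    "Neighborhood and Built Environment",
    "Social and Community Context",
)

#: Relation label used when no relation extractor is supplied.
FALLBACK_RELATION = "associated_with"


# ---------------------------------------------------------------------------
# documents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mention:
    sentence_index: int
    surface: str
    entity_id: str
    entity_type: str


@dataclass
class Document:
    """One abstract: ordered sentences plus located entity mentions."""

    doc_id: str
    sentences: list[str]
    mentions: list[Mention] = field(default_factory=list)

    def validate(self) -> None:
        for m in self.mentions:
            if not 0 <= m.sentence_index < len(self.sentences):
                raise ValueError(
                    f"document {self.doc_id}: mention {m.entity_id!r} has "
                    f"sentence index {m.sentence_index} out of range"
                )
            if m.surface not in self.sentences[m.sentence_index]:
                raise ValueError(
                    f"document {self.doc_id}: surface {m.surface!r} not found "
                    f"in sentence {m.sentence_index}"
                )


@dataclass(frozen=True)
class SDoHEntity:
    """A term accepted as a social determinant, with its category assignment."""

    entity_id: str
    surface: str
    main_category: str
    subcategory: str

    def __post_init__(self) -> None:
        if self.main_category not in SDOH_CATEGORIES:
            raise ValueError(
                f"{self.main_category!r} is not one of the five SDoH categories"
            )
        if not self.subcategory:
            raise ValueError("subcategory must be non-empty")


@dataclass(frozen=True)
class CooccurrenceRecord:
    bio_id: str
    sdoh_id: str
    n_both: int
    n_a: int
    n_b: int

    @property
    def score(self) -> float:
        return self.n_both / max(self.n_a, self.n_b)


# ---------------------------------------------------------------------------
# text cleaning and segmentation
# ---------------------------------------------------------------------------

_NON_ALNUM = re.compile(r"[^a-z0-9\s]+")
_WS = re.compile(r"\s+")
_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")


def clean_text(raw: str) -> str:
    """Lowercase, strip punctuation/special characters, collapse whitespace.

    Idempotent: applying twice equals applying once.
    """
    text = raw.lower()
    text = _NON_ALNUM.sub(" ", text)
    return _WS.sub(" ", text).strip()


def split_sentences(raw: str) -> list[str]:
    """Split on sentence-final punctuation (before cleaning)."""
    parts = _SENT_SPLIT.split(raw.strip())
    return [p for p in (s.strip() for s in parts) if p]


# ---------------------------------------------------------------------------
# pluggable service interfaces
# ---------------------------------------------------------------------------

class Recognizer(ABC):
    """Named-entity recognition contract: text -> (surface, id, type) hits."""

    @abstractmethod
    def recognize(self, text: str) -> list[tuple[str, str, str]]:
        """Return (surface form, entity id, entity type) for each hit in text."""


class Classifier(ABC):
    """Two-pass SDoH classification contract.

    ``classify`` returns ``(main_category, subcategory)`` for an accepted term
    and ``None`` for a rejected (non-SDoH) term.
    """

    @abstractmethod
    def classify(self, term: str) -> tuple[str, str] | None: ...

    def classify_batch(
        self, terms: Sequence[str]
    ) -> list[tuple[str, str] | None]:
        """Classify all terms in one call (no per-record context leaks)."""
        return [self.classify(t) for t in terms]


class RelationExtractor(ABC):
    """Relation labelling contract for a co-occurring entity pair."""

    @abstractmethod
    def relate(self, doc: Document, bio_id: str, sdoh_id: str) -> str: ...


class DictionaryRecognizer(Recognizer):
    """Exact surface matching against a vocabulary of cleaned terms."""

    def __init__(self, vocabulary: dict[str, tuple[str, str]]):
        #: cleaned surface form -> (entity id, entity type)
        self.vocabulary = {clean_text(k): v for k, v in vocabulary.items()}

    def recognize(self, text: str) -> list[tuple[str, str, str]]:
        cleaned = clean_text(text)
        padded = f" {cleaned} "
        hits = []
        for surface, (eid, etype) in sorted(self.vocabulary.items()):
            if f" {surface} " in padded:
                hits.append((surface, eid, etype))
        return hits


class DictionaryClassifier(Classifier):
    """Lookup-table classifier: term -> (main category, subcategory) or reject."""

    def __init__(self, table: dict[str, tuple[str, str]]):
        self.table = {clean_text(k): v for k, v in table.items()}

    def classify(self, term: str) -> tuple[str, str] | None:
        return self.table.get(clean_text(term))


class StaticRelationExtractor(RelationExtractor):
    def __init__(self, label: str = FALLBACK_RELATION):
        self.label = label

    def relate(self, doc: Document, bio_id: str, sdoh_id: str) -> str:
        return self.label


# ---------------------------------------------------------------------------
# SDoH classification (two passes over the aggregated candidate list)
# ---------------------------------------------------------------------------

def classify_sdoh(
    candidates: Sequence[str], classifier: Classifier
) -> list[SDoHEntity]:
    """Filter candidate terms to SDoH entities via two classification passes.

    Pass 1 assigns each term one of the five main categories, dropping any
    term the classifier rejects (the rationale: a term fitting no category is
    unlikely to be a genuine social determinant).  Pass 2 assigns
    subcategories to the survivors.  All terms go to the classifier in one
    batch; output order follows input order; classifier failures drop the
    term with a warning rather than aborting the run.
    """
    if not candidates:
        return []
    try:
        results = classifier.classify_batch(list(candidates))
    except Exception:
        # batch-level failure: retry per term so one bad term cannot sink all
        results = []
        for term in candidates:
            try:
                results.append(classifier.classify(term))
            except Exception:
                logger.warning("classifier failed on term %r; dropping", term)
                results.append(None)

    # pass 1: main-category filter
    survivors: list[tuple[str, str, str]] = []
    n_rejected = 0
    for term, res in zip(candidates, results):
        if res is None:
            n_rejected += 1
            continue
        main, sub = res
        survivors.append((term, main, sub))
    if n_rejected:
        logger.info(
            "classify_sdoh: rejected %d of %d candidate terms",
            n_rejected, len(candidates),
        )

    # pass 2: subcategory assignment for survivors
    out: list[SDoHEntity] = []
    for term, main, sub in survivors:
        try:
            out.append(
                SDoHEntity(entity_id=term, surface=term,
                           main_category=main, subcategory=sub)
            )
        except ValueError:
            logger.warning("invalid classification for %r: (%r, %r); dropping",
                           term, main, sub)
    return out


# ---------------------------------------------------------------------------
# co-occurrence scoring and triplet extraction
# ---------------------------------------------------------------------------

class UndefinedScoreError(ValueError):
    pass


def _sentence_sets(
    docs: Iterable[Document],
) -> dict[str, set[tuple[str, int]]]:
    """Map entity id -> set of (doc id, sentence index) containing it."""
    out: dict[str, set[tuple[str, int]]] = {}
    for doc in docs:
        for m in doc.mentions:
            out.setdefault(m.entity_id, set()).add((doc.doc_id, m.sentence_index))
    return out


def count_sentence_cooccurrence(
    docs: Sequence[Document], pair: tuple[str, str]
) -> CooccurrenceRecord:
    """Sentence co-mention counts and overlap score for one entity pair.

    Counts run over all sentences of all documents.  Raises
    :class:`UndefinedScoreError` when neither entity appears anywhere (the
    denominator would be zero).
    """
    a, b = pair
    sets = _sentence_sets(docs)
    sa, sb = sets.get(a, set()), sets.get(b, set())
    if not sa and not sb:
        raise UndefinedScoreError(
            f"neither {a!r} nor {b!r} appears in any sentence; score undefined"
        )
    return CooccurrenceRecord(
        bio_id=a, sdoh_id=b,
        n_both=len(sa & sb), n_a=len(sa), n_b=len(sb),
    )


def extract_literature_triplets(
    docs: Sequence[Document],
    bio_ids: Sequence[str] | None = None,
    sdoh_ids: Sequence[str] | None = None,
    relation_extractor: RelationExtractor | None = None,
    threshold: float = 0.5,
    bio_type_of: dict[str, str] | None = None,
) -> list[Triplet]:
    """Mine (bio entity, relation, SDoH entity) triplets from a corpus.

    For every (bio, sdoh) pair present in the corpus the sentence-level
    co-occurrence record is computed; pairs with ``score >= threshold``
    (inclusive boundary) are emitted as triplets carrying the score and the
    provenance doc ids of co-mention sentences.  Relation labels come from
    ``relation_extractor``; without one a single canonical fallback label is
    used so output is deterministic.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    sets = _sentence_sets(docs)
    type_of: dict[str, str] = {}
    for doc in docs:
        for m in doc.mentions:
            type_of.setdefault(m.entity_id, m.entity_type)
    if bio_type_of:
        type_of.update(bio_type_of)

    if bio_ids is None:
        bio_ids = sorted(e for e, t in type_of.items() if t != "sdoh")
    if sdoh_ids is None:
        sdoh_ids = sorted(e for e, t in type_of.items() if t == "sdoh")

    extractor = relation_extractor or StaticRelationExtractor()
    doc_by_id = {d.doc_id: d for d in docs}

    triplets: list[Triplet] = []
    for bio in sorted(bio_ids):
        sa = sets.get(bio)
        if not sa:
            continue
        for sdoh in sorted(sdoh_ids):
            sb = sets.get(sdoh)
            if not sb:
                continue
            both = sa & sb
            if not both:
                continue
            score = len(both) / max(len(sa), len(sb))
            if score < threshold:
                continue
            prov = tuple(sorted({doc_id for doc_id, _ in both}))
            relation = extractor.relate(doc_by_id[prov[0]], bio, sdoh)
            triplets.append(
                Triplet(
                    head=bio, relation=relation, tail=sdoh,
                    head_type=type_of.get(bio, "bio"), tail_type="sdoh",
                    weight=float(len(both)), score=score, provenance=prov,
                )
            )
    return triplets
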