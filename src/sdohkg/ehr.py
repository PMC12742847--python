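"""Population-level EHR knowledge graph.

Builds a knowledge graph from patient records: cohort selection by ICD-9
diagnosis code, per-patient typed entity sets (diagnoses, drugs, the six
demographic attributes, SDoH terms mined from note text), all-pairs
co-assignment counting across patients, and a minimum-frequency filter
(pairs seen in fewer than ``min_freq`` patients are dropped; default 10).
No patient nodes appear in the output graph — it is population-level.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .kg import KnowledgeGraph, Triplet
from .textmine import Classifier, classify_sdoh, clean_text

logger = logging.getLogger(__name__)

DEMOGRAPHIC_ATTRIBUTES = (
    "age", "ethnicity", "religion", "marital_status", "gender", "insurance",
)

#: ICD-9 codes for AD and related dementias (vascular, senile, Lewy body...).
DEFAULT_TARGET_ICD9 = (
    "3310", "2900", "2901", "2902", "2903", "2904",
    "3311", "3312", "33182", "2941", "4380",
)

#: Default decade bins for the age attribute.
DEFAULT_AGE_BINS = (0, 50, 60, 70, 80, 90, 200)


@dataclass
class PatientRecord:
    """One EHR subject: demographics, diagnosis codes, drugs, note text."""

    subject_id: str
    demographics: dict
    diagnoses: list[str]
    drugs: list[str] = field(default_factory=list)
    note_text: str = ""

    def __post_init__(self) -> None:
        missing = [a for a in DEMOGRAPHIC_ATTRIBUTES if a not in self.demographics]
        if missing:
            raise ValueError(
                f"patient {self.subject_id}: missing demographic attributes {missing}"
            )


def select_cohort(
    records: Sequence[PatientRecord],
    target_codes: Iterable[str] = DEFAULT_TARGET_ICD9,
) -> list[PatientRecord]:
    """Records with at least one diagnosis code in ``target_codes``; order kept."""
    codes = set(target_codes)
    if not codes:
        raise ValueError("target_codes must be non-empty")
    return [r for r in records if any(c in codes for c in r.diagnoses)]


def bucket_age(age, bins: Sequence[int] = DEFAULT_AGE_BINS) -> str:
    """Map a raw age to its bin label, e.g. 72 -> '70-79' with decade bins."""
    age = float(age)
    for lo, hi in zip(bins[:-1], bins[1:]):
        if lo <= age < hi:
            return f"{lo}-{hi - 1}"
    return f">={bins[-1]}"


class DictionarySDoHExtractor:
    """SDoH extraction chain for note text: scan a vocabulary over the cleaned
    note, then run the surviving terms through a two-pass classifier."""

    def __init__(self, classifier: Classifier, vocabulary: Iterable[str]):
        self.classifier = classifier
        self.vocabulary = sorted({clean_text(v) for v in vocabulary})

    def __call__(self, note_text: str) -> list[str]:
        padded = f" {clean_text(note_text)} "
        candidates = [v for v in self.vocabulary if f" {v} " in padded]
        return [e.entity_id for e in classify_sdoh(candidates, self.classifier)]


def patient_entity_set(
    record: PatientRecord,
    sdoh_extractor: Callable[[str], Iterable[str]] | None = None,
    age_bins: Sequence[int] = DEFAULT_AGE_BINS,
) -> set[tuple[str, str]]:
    """Typed entity set for one patient: (entity id, entity type) pairs.

    One entity per diagnosis code (type ``disease``), per drug (``drug``),
    per demographic attribute-value (typed by the attribute; age bucketed
    into ``age_bins``), and per SDoH term the extractor accepts from the
    note text (``sdoh``).  Extractor failure leaves the SDoH subset empty
    for that patient (logged), it does not abort the build.
    """
    entities: set[tuple[str, str]] = set()
    for code in record.diagnoses:
        entities.add((str(code), "disease"))
    for drug in record.drugs:
        entities.add((clean_text(drug), "drug"))
    for attr in DEMOGRAPHIC_ATTRIBUTES:
        value = record.demographics[attr]
        if attr == "age":
            value = bucket_age(value, age_bins)
        entities.add((f"{attr}={value}", attr))
    if sdoh_extractor is not None and record.note_text:
        try:
            for term in sdoh_extractor(record.note_text):
                entities.add((term, "sdoh"))
        except Exception:
            logger.warning(
                "SDoH extraction failed for patient %s; omitting SDoH entities",
                record.subject_id,
            )
    return entities


def build_population_kg(
    entity_sets: Sequence[set[tuple[str, str]]],
    min_freq: int = 10,
) -> KnowledgeGraph:
    """Aggregate per-patient entity sets into a frequency-filtered KG.

    For every unordered pair of distinct entities co-assigned within at least
    one patient, frequency = number of patients containing both; pairs with
    frequency >= ``min_freq`` become edges (weight = frequency; triplets seen
    in fewer patients are excluded).  The relation label is the canonical
    ordered pair of endpoint types, e.g. ``disease_drug``.
    """
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    counts: Counter[tuple[tuple[str, str], tuple[str, str]]] = Counter()
    for entities in entity_sets:
        for a, b in itertools.combinations(sorted(entities), 2):
            counts[(a, b)] += 1

    kg = KnowledgeGraph()
    for ((id_a, type_a), (id_b, type_b)), freq in sorted(counts.items()):
        if freq < min_freq:
            continue
        # canonical order: by type then id, so the relation label is stable
        if (type_a, id_a) <= (type_b, id_b):
            head, htype, tail, ttype = id_a, type_a, id_b, type_b
        else:
            head, htype, tail, ttype = id_b, type_b, id_a, type_a
        kg.add_edge(
            Triplet(head, f"{htype}_{ttype}", tail,
                    head_type=htype, tail_type=ttype, weight=float(freq))
        )
    return kg
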