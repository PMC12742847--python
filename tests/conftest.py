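import numpy as np
import pytest

from sdohkg.kg import KnowledgeGraph, Triplet
from sdohkg.textmine import Document, Mention


def make_doc(doc_id: str, sentence_entities: list[list[tuple[str, str]]]) -> Document:
    """Build a Document from per-sentence (entity id, entity type) lists."""
    sentences = []
    mentions = []
    for s, ents in enumerate(sentence_entities):
        sentences.append("mentions " + " and ".join(e for e, _ in ents))
        for eid, etype in ents:
            mentions.append(Mention(s, eid, eid, etype))
    doc = Document(doc_id=doc_id, sentences=sentences, mentions=mentions)
    doc.validate()
    return doc


def make_kg(edges, node_types=None) -> KnowledgeGraph:
    """Build a KnowledgeGraph from (head, relation, tail) or Triplet entries.

    ``node_types`` maps node id -> type; unlisted nodes default to 'entity'.
    """
    node_types = node_types or {}
    kg = KnowledgeGraph()
    for e in edges:
        if not isinstance(e, Triplet):
            h, r, t = e
            e = Triplet(h, r, t,
                        head_type=node_types.get(h, "entity"),
                        tail_type=node_types.get(t, "entity"))
        kg.add_edge(e)
    return kg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
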