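"""Knowledge-graph fusion: CUI alignment, merging, mirrored-edge removal.

Entities of configured shared types (default drug and disease) are normalized
to UMLS-style Concept Unique Identifiers via a static two-column mapping
table; nodes with equal (type, identifier) keys collapse into one merged
node, so the same concept mined from literature and from EHR becomes a single
node in the fused graph.  Entities the table cannot map keep their original
identifiers, flagged unmapped, so no information is lost.  After fusion,
edges present in both directions between the same node pair under the same
relation are collapsed to a single canonical direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .kg import KnowledgeGraph, Triplet


class AlignmentError(ValueError):
    pass


DEFAULT_SHARED_TYPES = ("drug", "disease")


@dataclass(frozen=True)
class EntityKey:
    """Identity of an entity for alignment: type + (CUI or original id).

    Keys compare equal iff both the type and the identifier match; whether
    the identifier is a CUI or an unmapped original id participates in the
    identity (two different identifier kinds never collide in practice
    because CUIs live in their own namespace).
    """

    entity_type: str
    identifier: str
    is_cui: bool = field(compare=False, default=False)

    @property
    def unmapped(self) -> bool:
        return not self.is_cui


def normalize_to_cui(
    entity_id: str, entity_type: str, mapping_table: Mapping[str, str]
) -> EntityKey:
    """CUI-keyed identity when the table maps the entity, else the original id."""
    cui = mapping_table.get(entity_id)
    if cui is not None:
        return EntityKey(entity_type, cui, is_cui=True)
    return EntityKey(entity_type, entity_id, is_cui=False)


@dataclass
class MergeMap:
    """Where every input node went: (graph label, original id) -> merged id."""

    mapping: dict[tuple[str, str], str]
    merged_pairs: list[tuple[str, str]]  # (id in A, id in B) that collapsed


def _entity_keys(
    kg: KnowledgeGraph,
    mapping_table: Mapping[str, str],
    shared_types: tuple[str, ...],
) -> dict[str, EntityKey]:
    keys = {}
    for node_id, node_type in kg.node_types.items():
        if node_type in shared_types:
            keys[node_id] = normalize_to_cui(node_id, node_type, mapping_table)
        else:
            keys[node_id] = EntityKey(node_type, node_id, is_cui=False)
    return keys


def align_and_merge(
    kg_a: KnowledgeGraph,
    kg_b: KnowledgeGraph,
    mapping_table: Mapping[str, str] | None = None,
    shared_types: Iterable[str] = DEFAULT_SHARED_TYPES,
) -> tuple[KnowledgeGraph, MergeMap]:
    """Merge two KGs, collapsing nodes whose entity keys coincide.

    CUI normalization is attempted only for ``shared_types``; other types
    align on (type, original id).  The merged node count is
    ``|A| + |B| - len(merged_pairs)``.  Exact duplicate (head, relation,
    tail) edges after id rewriting are deduplicated, keeping the maximum
    weight and the union of provenance; parallel edges with different
    relation labels stay distinct.  A mapping that sends entities of two
    different types to the same CUI raises :class:`AlignmentError`.
    """
    mapping_table = mapping_table or {}
    shared = tuple(shared_types)
    keys_a = _entity_keys(kg_a, mapping_table, shared)
    keys_b = _entity_keys(kg_b, mapping_table, shared)

    cui_types: dict[str, set[str]] = {}
    for keys in (keys_a, keys_b):
        for key in keys.values():
            if key.is_cui:
                cui_types.setdefault(key.identifier, set()).add(key.entity_type)
    for cui, types in sorted(cui_types.items()):
        if len(types) > 1:
            raise AlignmentError(
                f"CUI {cui} maps entities of different types {sorted(types)}"
            )

    def merged_id(key: EntityKey) -> str:
        return key.identifier

    merged = KnowledgeGraph()
    node_map: dict[tuple[str, str], str] = {}
    for label, kg, keys in (("A", kg_a, keys_a), ("B", kg_b, keys_b)):
        for node_id in kg.node_types:
            key = keys[node_id]
            mid = merged_id(key)
            merged.add_node(mid, key.entity_type)
            node_map[(label, node_id)] = mid

    by_key_a = {keys_a[n]: n for n in kg_a.node_types}
    merged_pairs = [
        (by_key_a[keys_b[n]], n) for n in sorted(kg_b.node_types)
        if keys_b[n] in by_key_a
    ]

    # rewrite edges and deduplicate exact (head, relation, tail) repeats
    dedup: dict[tuple[str, str, str], Triplet] = {}
    for label, kg in (("A", kg_a), ("B", kg_b)):
        for e in kg:
            h = node_map[(label, e.head)]
            t = node_map[(label, e.tail)]
            new = replace(e, head=h, tail=t,
                          head_type=merged.node_types[h],
                          tail_type=merged.node_types[t])
            prior = dedup.get(new.key)
            if prior is None:
                dedup[new.key] = new
            else:
                dedup[new.key] = replace(
                    prior,
                    weight=max(prior.weight, new.weight),
                    score=max(
                        (s for s in (prior.score, new.score) if s is not None),
                        default=None,
                    ),
                    provenance=tuple(sorted(set(prior.provenance) | set(new.provenance))),
                )
    for e in dedup.values():
        merged.add_edge(e)
    return merged, MergeMap(mapping=node_map, merged_pairs=merged_pairs)


def remove_mirrored_edges(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Collapse backward edges: one direction per mirrored (pair, relation).

    When both (a, r, b) and (b, r, a) are present, the direction whose head
    is the lexicographically smaller node id survives; single-direction
    edges are untouched.  Idempotent.
    """
    keys = kg.edge_keys()
    out = KnowledgeGraph()
    out.node_types = dict(kg.node_types)
    seen: set[tuple[str, str, str]] = set()
    for e in kg:
        mirror = (e.tail, e.relation, e.head)
        if mirror in keys and e.head != e.tail:
            canonical_head = min(e.head, e.tail)
            if e.head != canonical_head:
                continue  # the mirror in canonical direction survives instead
        if e.key in seen:
            continue  # exact repeats of a mirrored edge collapse too
        seen.add(e.key)
        out.edges.append(e)
    return out


def read_mapping_table(path) -> dict[str, str]:
    """Two-column TSV (term/id, CUI) -> dict; '#' comment lines skipped."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            table[parts[0]] = parts[1]
    return table
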