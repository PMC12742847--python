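"""Core knowledge-graph data model.

A knowledge graph here is a typed node set plus a typed edge multiset.  Node
ids are opaque strings; each node carries a type label (``gene``, ``disease``,
``drug``, ``sdoh``, ...).  Edges are directed triplets (head, relation, tail)
with an optional weight (e.g. a patient-frequency count), an optional
co-occurrence score, and provenance (document ids the triplet was mined from).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Triplet:
    """A (head, relation, tail) assertion — the atomic KG element."""

    head: str
    relation: str
    tail: str
    head_type: str = ""
    tail_type: str = ""
    weight: float = 1.0
    score: float | None = None
    provenance: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.head, self.relation, self.tail)


class KnowledgeGraphError(ValueError):
    pass


class KnowledgeGraph:
    """Typed node set + typed edge multiset with metadata.

    Nodes are stored as ``id -> type``; edges as a list of :class:`Triplet`.
    Equality compares the node mapping and the edge multiset (order-free).
    """

    def __init__(self) -> None:
        self.node_types: dict[str, str] = {}
        self.edges: list[Triplet] = []

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, node_type: str) -> None:
        existing = self.node_types.get(node_id)
        if existing is not None and existing != node_type:
            raise KnowledgeGraphError(
                f"node {node_id!r} already present with type {existing!r}, "
                f"cannot re-add as {node_type!r}"
            )
        self.node_types[node_id] = node_type

    def add_edge(self, edge: Triplet) -> None:
        for endpoint, etype in ((edge.head, edge.head_type), (edge.tail, edge.tail_type)):
            if endpoint not in self.node_types:
                if not etype:
                    raise KnowledgeGraphError(
                        f"edge endpoint {endpoint!r} has no registered node and no type"
                    )
                self.add_node(endpoint, etype)
        # keep edge endpoint types consistent with the node table
        edge = replace(
            edge,
            head_type=self.node_types[edge.head],
            tail_type=self.node_types[edge.tail],
        )
        self.edges.append(edge)

    # -- queries ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_types)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self.node_types.items() if t == node_type)

    def relations(self) -> list[str]:
        return sorted({e.relation for e in self.edges})

    def edges_of_relation(self, relation: str) -> list[Triplet]:
        return [e for e in self.edges if e.relation == relation]

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {e.key for e in self.edges}

    def undirected_pairs(self) -> set[frozenset[str]]:
        return {frozenset((e.head, e.tail)) for e in self.edges}

    def has_edge(self, head: str, relation: str, tail: str) -> bool:
        return (head, relation, tail) in self.edge_keys()

    def __iter__(self) -> Iterator[Triplet]:
        return iter(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self.node_types == other.node_types
            and sorted(self.edges, key=lambda e: (e.key, e.weight)) ==
            sorted(other.edges, key=lambda e: (e.key, e.weight))
        )

    def __repr__(self) -> str:
        return f"<KnowledgeGraph: {self.n_nodes} nodes, {self.n_edges} edges>"

    def copy(self) -> "KnowledgeGraph":
        out = KnowledgeGraph()
        out.node_types = dict(self.node_types)
        out.edges = list(self.edges)
        return out

    # -- derived graphs ---------------------------------------------------
    def without_edges(self, keys: Iterable[tuple[str, str, str]]) -> "KnowledgeGraph":
        """Copy with the listed (head, relation, tail) edges removed.

        Node set is preserved so embeddings stay defined for masked nodes.
        """
        drop = set(keys)
        out = KnowledgeGraph()
        out.node_types = dict(self.node_types)
        out.edges = [e for e in self.edges if e.key not in drop]
        return out

    def without_node_type(self, node_type: str) -> "KnowledgeGraph":
        """Copy with all nodes of ``node_type`` (and their incident edges) removed."""
        out = KnowledgeGraph()
        out.node_types = {n: t for n, t in self.node_types.items() if t != node_type}
        out.edges = [
            e for e in self.edges
            if e.head in out.node_types and e.tail in out.node_types
        ]
        return out


def from_triplets(triplets: Iterable[Triplet]) -> KnowledgeGraph:
    kg = KnowledgeGraph()
    for t in triplets:
        kg.add_edge(t)
    return kg
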