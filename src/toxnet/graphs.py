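"""Core network data model shared by every subnetwork-extraction strategy.

Two scaffolds are used throughout: a confidence-weighted undirected
protein interactome, and a heterogeneous network that adds drug, disease
and biological-process nodes with per-type scalar weights.  Edges are
stored undirected in both; in the heterogeneous walk the bias comes from
node-type weights, not from edge direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import ValidationError
from .netio import EdgeRecord

NODE_TYPES = ("protein", "drug", "disease", "biological_process")

#: score given to process-process and process-protein links when no
#: explicit confidence is available
DEFAULT_PROCESS_CONFIDENCE = 0.4

#: positivity floor used when clipping scaled activities / costs
EPSILON = 1e-6

__all__ = [
    "NODE_TYPES",
    "DEFAULT_PROCESS_CONFIDENCE",
    "EPSILON",
    "WeightedInteractome",
    "HeterogeneousNetwork",
    "MethodResult",
    "largest_connected_component",
    "scale_activity_to_confidence",
    "assemble_heterogeneous",
]


class WeightedInteractome:
    """Undirected protein graph with edge confidences in (0, 1]."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self._validate()

    def _validate(self):
        for a, b, data in self.graph.edges(data=True):
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            c = data.get("confidence")
            if c is None or not (0.0 < c <= 1.0):
                raise ValidationError(f"edge ({a}, {b}) confidence {c!r} outside (0, 1]")

    @classmethod
    def from_edge_records(cls, records: Iterable[EdgeRecord]) -> "WeightedInteractome":
        g = nx.Graph()
        for r in records:
            prev = g.get_edge_data(r.node_a, r.node_b)
            if prev is None or r.confidence > prev["confidence"]:
                g.add_edge(r.node_a, r.node_b, confidence=r.confidence)
        return cls(g)

    def to_edge_records(self) -> list[EdgeRecord]:
        return [
            EdgeRecord(a, b, d["confidence"])
            for a, b, d in sorted(self.graph.edges(data=True))
        ]

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    def sorted_nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def confidence(self, a: str, b: str) -> float:
        return self.graph[a][b]["confidence"]

    def __contains__(self, node) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightedInteractome):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and {frozenset(e): d["confidence"] for *e, d in self.graph.edges(data=True)}
            == {frozenset(e): d["confidence"] for *e, d in other.graph.edges(data=True)}
        )


@dataclass
class HeterogeneousNetwork:
    """Typed multipartite scaffold for the biased heterogeneous walk.

    ``type_weights`` w_t encode the relative importance of landing on a
    node of type t; they default to 1.0 (neutral) for every type since
    optimal values are application-specific and user-supplied.
    """

    graph: nx.Graph
    type_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for t in NODE_TYPES:
            self.type_weights.setdefault(t, 1.0)
        for t, w in self.type_weights.items():
            if t not in NODE_TYPES:
                raise ValidationError(f"unknown node type in type_weights: {t!r}")
            if w <= 0:
                raise ValidationError(f"type weight for {t!r} must be > 0, got {w}")
        for n, data in self.graph.nodes(data=True):
            if data.get("type") not in NODE_TYPES:
                raise ValidationError(f"node {n!r} has no registered type")
        for a, b, data in self.graph.edges(data=True):
            c = data.get("confidence")
            if c is None or not (0.0 < c <= 1.0):
                raise ValidationError(f"edge ({a}, {b}) confidence {c!r} outside (0, 1]")

    def node_type(self, n: str) -> str:
        return self.graph.nodes[n]["type"]

    def nodes_of_type(self, node_type: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["type"] == node_type}

    def sorted_nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class MethodResult:
    """A strategy's selected gene set with provenance.

    The unit of cross-method comparison: method name, the genes it
    selected, optional per-gene scores and the run parameters used.
    """

    method_name: str
    genes: frozenset[str]
    scores: Mapping[str, float] | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))


def largest_connected_component(interactome: WeightedInteractome) -> WeightedInteractome:
    """Return the LCC used as the scaffold for clustering and propagation.

    Ties between equally sized components are broken by the
    lexicographically smallest member node, making the result
    deterministic.  Idempotent.
    """
    g = interactome.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot take the largest connected component of an empty graph")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return WeightedInteractome(g.subgraph(comps[0]).copy())


def scale_activity_to_confidence(pchembl_like: float, epsilon: float = EPSILON) -> float:
    """Scale a pChembl-like activity (−log of activity) onto (0, 1].

    Division by 10 puts bioactivity values on the same scale as
    interaction confidence scores; the result is clipped to
    [epsilon, 1].
    """
    if pchembl_like < 0:
        raise ValidationError(f"activity value must be ≥ 0, got {pchembl_like}")
    return min(1.0, max(epsilon, pchembl_like / 10.0))


def assemble_heterogeneous(
    node_table: Mapping[str, str],
    edge_table: Iterable[tuple[str, str, float | None]],
    type_weights: Mapping[str, float] | None = None,
    default_process_confidence: float = DEFAULT_PROCESS_CONFIDENCE,
) -> HeterogeneousNetwork:
    """Build a heterogeneous network from a node-type table and edges.

    Edges given without an explicit confidence must touch a
    biological_process node and receive ``default_process_confidence``;
    explicitly provided confidences are never changed.
    """
    g = nx.Graph()
    for nid, ntype in node_table.items():
        if ntype not in NODE_TYPES:
            raise ValidationError(f"node {nid!r} has unknown type {ntype!r}")
        g.add_node(nid, type=ntype)
    for a, b, conf in edge_table:
        if a not in node_table or b not in node_table:
            raise ValidationError(f"edge ({a!r}, {b!r}) references an unregistered node")
        if conf is None:
            if "biological_process" not in (node_table[a], node_table[b]):
                raise ValidationError(
                    f"edge ({a!r}, {b!r}) lacks a confidence and touches no biological_process node"
                )
            conf = default_process_confidence
        g.add_edge(a, b, confidence=float(conf))
    return HeterogeneousNetwork(g, dict(type_weights) if type_weights else {})
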