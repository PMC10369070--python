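"""Minimum-cost subnetwork connecting seed genes.

Edge confidences become costs (1 − confidence by default); edges
touching a preferred linker gene (disease-associated genes) are
discounted by a multiplicative factor λ ∈ (0, 1], steering the
connecting paths through the disease neighbourhood.  The subnetwork is
a 2-approximate Steiner tree obtained by the metric-closure (shortest
paths between terminals → MST → pruning) construction; on trees this is
exactly optimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms.approximation import steiner_tree as _nx_steiner_tree

from .errors import ValidationError
from .graphs import EPSILON, MethodResult, WeightedInteractome

logger = logging.getLogger(__name__)

__all__ = ["SteinerConfig", "Subnetwork", "edge_costs", "steiner_subnetwork", "steiner_method_result"]

COST_TRANSFORMS = ("one_minus_confidence", "reciprocal")


@dataclass(frozen=True)
class SteinerConfig:
    seeds: frozenset[str]
    preferred_linkers: frozenset[str] = frozenset()
    linker_discount: float = 0.5
    cost_transform: str = "one_minus_confidence"

    def __post_init__(self):
        object.__setattr__(self, "seeds", frozenset(self.seeds))
        object.__setattr__(self, "preferred_linkers", frozenset(self.preferred_linkers))
        if not (0.0 < self.linker_discount <= 1.0):
            raise ValidationError(f"linker discount must be in (0, 1], got {self.linker_discount}")
        if self.cost_transform not in COST_TRANSFORMS:
            raise ValidationError(f"unknown cost transform {self.cost_transform!r}")


@dataclass
class Subnetwork:
    graph: nx.Graph
    total_cost: float
    roles: dict[str, str] = field(default_factory=dict)
    unreachable_seeds: frozenset[str] = frozenset()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())


def edge_costs(interactome: WeightedInteractome, config: SteinerConfig) -> dict[tuple[str, str], float]:
    """Per-edge cost > 0 under the configured transform and discount."""
    costs = {}
    for a, b, data in interactome.graph.edges(data=True):
        c = data["confidence"]
        if config.cost_transform == "one_minus_confidence":
            base = 1.0 - c
        else:
            base = 1.0 / c  # reciprocal transform
        if a in config.preferred_linkers or b in config.preferred_linkers:
            base *= config.linker_discount
        key = (a, b) if a <= b else (b, a)
        costs[key] = max(base, EPSILON)
    return costs


def steiner_subnetwork(interactome: WeightedInteractome, config: SteinerConfig) -> Subnetwork:
    """2-approximate Steiner tree over the discounted costs.

    Seeds that are missing from the graph or unreachable from the main
    seed component are reported, not fatal — mirroring scaffold losses
    in real runs.  Requires at least two reachable seeds.
    """
    g = interactome.graph
    present = sorted(config.seeds & set(g.nodes()))
    absent = config.seeds - set(present)
    if absent:
        logger.warning("steiner: %d seeds absent from the scaffold: %s",
                       len(absent), sorted(absent)[:5])
    # restrict to the component holding the most seeds (ties: smallest node)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(set(present) & c), min(c)))
    comp = comps[0] if comps else set()
    reachable = [s for s in present if s in comp]
    unreachable = frozenset(config.seeds) - frozenset(reachable)
    if len(reachable) < 2:
        raise ValidationError(f"need ≥2 reachable seeds, got {len(reachable)}")
    if unreachable:
        logger.warning("steiner: %d seeds unreachable, skipped", len(unreachable))

    work = g.subgraph(comp).copy()
    costs = edge_costs(WeightedInteractome(work), config)
    for (a, b), cost in costs.items():
        work[a][b]["cost"] = cost
    tree = _nx_steiner_tree(work, reachable, weight="cost", method="kou")
    sub = nx.Graph()
    total = 0.0
    for a, b in tree.edges():
        conf = work[a][b]["confidence"]
        cost = work[a][b]["cost"]
        sub.add_edge(a, b, confidence=conf, cost=cost)
        total += cost
    sub.add_nodes_from(reachable)
    roles = {}
    for n in sub.nodes():
        if n in config.seeds:
            roles[n] = "seed"
        elif n in config.preferred_linkers:
            roles[n] = "linker"
        else:
            roles[n] = "other"
        sub.nodes[n]["role"] = roles[n]
    return Subnetwork(graph=sub, total_cost=total, roles=roles, unreachable_seeds=unreachable)


def steiner_method_result(subnetwork: Subnetwork) -> MethodResult:
    role_counts: dict[str, int] = {}
    for r in subnetwork.roles.values():
        role_counts[r] = role_counts.get(r, 0) + 1
    return MethodResult(
        method_name="steiner",
        genes=frozenset(subnetwork.nodes),
        metadata={
            "total_cost": subnetwork.total_cost,
            "role_counts": role_counts,
            "unreachable_seeds": sorted(subnetwork.unreachable_seeds),
        },
    )
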