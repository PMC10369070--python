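"""Community detection on the interactome plus cluster selection rules.

A weighted, seeded community detector partitions the scaffold; clusters
are then selected by three conjunctive rules: size (strictly more than
``min_size`` genes), over-representation of at least one disease concept
gene set, and presence of drug targets.  The detector itself is
pluggable — the contribution of this module is the selection logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .enrichment import bh_adjust
from .errors import ValidationError
from .graphs import MethodResult, WeightedInteractome

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "ClusterSelection",
    "detect_communities",
    "filter_by_size",
    "select_clusters",
    "clustering_method_result",
]

Partition = dict[str, frozenset[str]]


@dataclass
class ClusterSelection:
    """Per-cluster selection flags and enrichment evidence."""

    selected: list[str]
    size_ok: dict[str, bool]
    disease_annotated: dict[str, bool]
    contains_targets: dict[str, bool]
    #: raw hypergeometric p per (cluster, concept)
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)
    #: BH-adjusted p per (cluster, concept), across all tests jointly
    q_values: dict[tuple[str, str], float] = field(default_factory=dict)


def _label_partition(communities) -> Partition:
    # deterministic ids: sort by (size desc, smallest member)
    comms = sorted((frozenset(c) for c in communities), key=lambda c: (-len(c), min(c)))
    return {f"C{i:04d}": c for i, c in enumerate(comms)}


def detect_communities(
    interactome: WeightedInteractome,
    method: str = "louvain",
    resolution: float = 1.0,
    rng_seed: int = 0,
) -> Partition:
    """Partition the interactome using edge confidences as weights."""
    g = interactome.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot cluster an empty graph")
    if method == "louvain":
        comms = nx.community.louvain_communities(
            g, weight="confidence", resolution=resolution, seed=rng_seed
        )
    elif method == "greedy_modularity":
        comms = nx.community.greedy_modularity_communities(
            g, weight="confidence", resolution=resolution
        )
    else:
        raise ValueError(f"unknown community detection method {method!r}")
    return _label_partition(comms)


def filter_by_size(partition: Partition, min_size_exclusive: int = 5) -> Partition:
    """Keep clusters with strictly more than ``min_size_exclusive`` genes."""
    return {cid: c for cid, c in partition.items() if len(c) > min_size_exclusive}


def select_clusters(
    partition: Partition,
    disease_sets: Mapping[str, set[str]],
    drug_targets: set[str],
    background: set[str],
    p_threshold: float = 0.05,
    min_size_exclusive: int = 5,
    correction: str = "bh",
    target_rule: str = "contain",
) -> ClusterSelection:
    """Apply the three conjunctive selection rules to a partition.

    disease_annotated: one-sided hypergeometric over-representation of
    ≥1 disease concept, BH-corrected across all (cluster × concept)
    tests by default (``correction="none"`` uses raw p-values).
    contains_targets: non-empty intersection with the drug targets, or
    target over-representation when ``target_rule="enrich"``.
    """
    if not background:
        raise ValidationError("background gene set is empty")
    for cid, c in partition.items():
        if not c <= background:
            raise ValidationError(f"cluster {cid} is not contained in the background")
    if correction not in ("bh", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if target_rule not in ("contain", "enrich"):
        raise ValueError(f"unknown target_rule {target_rule!r}")

    N = len(background)
    keys, raw = [], []
    for cid in sorted(partition):
        cluster = partition[cid]
        for concept in sorted(disease_sets):
            K = len(disease_sets[concept] & background)
            k = len(cluster & disease_sets[concept])
            p = float(hypergeom.sf(k - 1, N, K, len(cluster))) if K else 1.0
            keys.append((cid, concept))
            raw.append(min(p, 1.0))
    qvals = bh_adjust(np.array(raw)) if raw else np.array([])
    p_values = dict(zip(keys, raw))
    q_values = dict(zip(keys, qvals))
    effective = q_values if correction == "bh" else p_values

    target_bg = len(drug_targets & background)
    size_ok, disease_annot, has_targets = {}, {}, {}
    selected = []
    for cid in sorted(partition):
        cluster = partition[cid]
        size_ok[cid] = len(cluster) > min_size_exclusive
        disease_annot[cid] = any(
            effective[(cid, concept)] < p_threshold for concept in sorted(disease_sets)
        )
        if target_rule == "contain":
            has_targets[cid] = bool(cluster & drug_targets)
        else:
            k = len(cluster & drug_targets)
            p_t = float(hypergeom.sf(k - 1, N, target_bg, len(cluster))) if target_bg else 1.0
            has_targets[cid] = p_t < p_threshold
        if size_ok[cid] and disease_annot[cid] and has_targets[cid]:
            selected.append(cid)

    # selection order: ascending best enrichment p-value
    best_p = {
        cid: min((p_values[(cid, c)] for c in disease_sets), default=1.0) for cid in selected
    }
    selected.sort(key=lambda cid: (best_p[cid], cid))
    return ClusterSelection(
        selected=selected,
        size_ok=size_ok,
        disease_annotated=disease_annot,
        contains_targets=has_targets,
        p_values=p_values,
        q_values=q_values,
    )


def clustering_method_result(selection: ClusterSelection, partition: Partition) -> MethodResult:
    """Union of selected clusters, with per-cluster provenance."""
    genes: set[str] = set()
    provenance = {}
    for cid in selection.selected:
        genes |= partition[cid]
        provenance[cid] = len(partition[cid])
    if not genes:
        logger.warning("no clusters selected; clustering method result is empty")
    return MethodResult(
        method_name="clustering",
        genes=frozenset(genes),
        metadata={"selected_clusters": provenance, "n_clusters_total": len(partition)},
    )
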