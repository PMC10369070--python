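"""Cross-method integration.

Gene-level overlaps across the four strategies, novel candidate genes
(recovered by ≥2 methods, absent from both seed lists), combination of
per-method term clusters into groups under three rules, benchmarking
against a curated adverse-outcome gene set, and construction of the
consensus mechanism network from shortest paths.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationDB, TermCluster, jaccard
from .errors import ValidationError
from .graphs import HeterogeneousNetwork, MethodResult

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapReport",
    "NovelCandidateSet",
    "GOGroup",
    "overlap_report",
    "novel_candidates",
    "expression_filter",
    "group_go_clusters",
    "benchmark_against_aop",
    "consensus_network",
]


@dataclass
class OverlapReport:
    """Which methods support each gene, and summary overlap counts."""

    support: dict[str, frozenset[str]]  # gene -> supporting method names
    pairwise: dict[tuple[str, str], int]
    support_counts: dict[int, int]  # k -> number of genes supported by exactly k methods
    methods: tuple[str, ...]

    def genes_with_support(self, min_support: int) -> set[str]:
        return {g for g, m in self.support.items() if len(m) >= min_support}


@dataclass
class NovelCandidateSet:
    """Genes supported by ≥ min_support methods and absent from both seed lists."""

    genes: frozenset[str]
    provenance: dict[str, frozenset[str]]  # gene -> supporting methods
    min_support: int = 2
    expression_flags: dict[str, str] = field(default_factory=dict)


@dataclass
class GOGroup:
    """A merged group of per-method term clusters."""

    clusters: tuple[TermCluster, ...]
    satisfied_rules: frozenset[str]

    @property
    def methods(self) -> frozenset[str]:
        return frozenset(c.method_name for c in self.clusters)

    @property
    def terms(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c.members
        return frozenset(out)


def overlap_report(results: Sequence[MethodResult]) -> OverlapReport:
    """Tabulate per-gene method support and pairwise intersections."""
    if len(results) < 2:
        raise ValidationError("need at least two method results to compare")
    names = [r.method_name for r in results]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate method names: {names}")
    support: dict[str, set[str]] = {}
    for r in results:
        for g in r.genes:
            support.setdefault(g, set()).add(r.method_name)
    pairwise = {}
    for ra, rb in itertools.combinations(results, 2):
        key = tuple(sorted((ra.method_name, rb.method_name)))
        pairwise[key] = len(ra.genes & rb.genes)
    counts: dict[int, int] = {k: 0 for k in range(1, len(results) + 1)}
    for methods in support.values():
        counts[len(methods)] += 1
    return OverlapReport(
        support={g: frozenset(m) for g, m in support.items()},
        pairwise=pairwise,
        support_counts=counts,
        methods=tuple(names),
    )


def novel_candidates(
    report: OverlapReport,
    drug_targets: set[str],
    disease_genes: set[str],
    min_support: int = 2,
) -> NovelCandidateSet:
    """Multi-method genes not already tied to the drug or the outcome."""
    known = set(drug_targets) | set(disease_genes)
    picked = {
        g for g, methods in report.support.items()
        if len(methods) >= min_support and g not in known
    }
    return NovelCandidateSet(
        genes=frozenset(picked),
        provenance={g: report.support[g] for g in sorted(picked)},
        min_support=min_support,
    )


def expression_filter(
    candidates: NovelCandidateSet,
    expression_table: Mapping[str, float],
    threshold: float = 0.0,
) -> NovelCandidateSet:
    """Keep candidates expressed in the target tissue (NX strictly above
    the threshold); genes missing from the table are kept and flagged."""
    kept, flags = set(), {}
    for g in candidates.genes:
        if g not in expression_table:
            kept.add(g)
            flags[g] = "missing_from_expression_table"
        elif expression_table[g] > threshold:
            kept.add(g)
            flags[g] = "expressed"
        else:
            flags[g] = "not_expressed"
    n_missing = sum(1 for v in flags.values() if v == "missing_from_expression_table")
    if n_missing:
        logger.warning("expression_filter: %d candidates missing from the table, kept", n_missing)
    return NovelCandidateSet(
        genes=frozenset(kept),
        provenance={g: candidates.provenance[g] for g in sorted(kept)},
        min_support=candidates.min_support,
        expression_flags=flags,
    )


def _rules_for_group(
    clusters: Sequence[TermCluster], all_methods: frozenset[str], jaccard_threshold: float
) -> frozenset[str]:
    rules = set()
    # covering "every method" is only meaningful with ≥2 methods in play
    if len(all_methods) >= 2 and {c.method_name for c in clusters} >= all_methods:
        rules.add("all_four_methods")
    for a, b in itertools.combinations(clusters, 2):
        if jaccard(a.members, b.members) >= jaccard_threshold:
            rules.add("jaccard_04")
        if a.representative == b.representative:
            rules.add("shared_representative")
    return frozenset(rules)


def group_go_clusters(
    per_method_clusters: Mapping[str, Sequence[TermCluster]],
    jaccard_threshold: float = 0.4,
) -> list[GOGroup]:
    """Merge term clusters into groups by single linkage.

    Two clusters are linked when their term sets have a Jaccard index at
    or above the threshold (inclusive) or when they share the same
    representative term.  Each connected group is annotated with which
    of the three rules it satisfies: it contains clusters from every
    method, it was linked by Jaccard, or it was linked by a shared
    representative.  The output partitions the input clusters and is
    independent of input ordering.
    """
    tagged: list[TermCluster] = []
    for method in sorted(per_method_clusters):
        for c in per_method_clusters[method]:
            if c.method_name != method:
                c = TermCluster(c.representative, c.members, method)
            tagged.append(c)
    all_methods = frozenset(m for m in sorted(per_method_clusters) if per_method_clusters[m])

    link = nx.Graph()
    link.add_nodes_from(range(len(tagged)))
    for i, j in itertools.combinations(range(len(tagged)), 2):
        a, b = tagged[i], tagged[j]
        if a.representative == b.representative or jaccard(a.members, b.members) >= jaccard_threshold:
            link.add_edge(i, j)

    groups = []
    for comp in nx.connected_components(link):
        clusters = tuple(
            sorted((tagged[i] for i in comp), key=lambda c: (c.method_name, c.representative, sorted(c.members)))
        )
        groups.append(
            GOGroup(clusters=clusters, satisfied_rules=_rules_for_group(clusters, all_methods, jaccard_threshold))
        )
    groups.sort(key=lambda g: (-len(g.clusters), sorted(g.terms)))
    return groups


def selected_groups(groups: Iterable[GOGroup]) -> list[GOGroup]:
    """Groups satisfying at least one of the three combination rules."""
    return [g for g in groups if g.satisfied_rules]


def benchmark_against_aop(
    results: Sequence[MethodResult],
    aop_genes: set[str],
    aop_clusters: Sequence[TermCluster] = (),
    per_method_clusters: Mapping[str, Sequence[TermCluster]] | None = None,
    jaccard_flag_threshold: float = 0.4,
) -> pd.DataFrame:
    """Per-method recovery of the benchmark gene set, plus term-cluster
    similarity to the benchmark's clusters where provided."""
    if not aop_genes:
        raise ValidationError("benchmark gene set is empty")
    rows = []
    for r in results:
        inter = len(r.genes & aop_genes)
        best_ji, n_similar = 0.0, 0
        if aop_clusters and per_method_clusters and r.method_name in per_method_clusters:
            for mc in per_method_clusters[r.method_name]:
                for ac in aop_clusters:
                    ji = jaccard(mc.members, ac.members)
                    best_ji = max(best_ji, ji)
                    if ji > jaccard_flag_threshold:
                        n_similar += 1
        rows.append(
            dict(
                method=r.method_name,
                total_genes=len(r.genes),
                aop_overlap=inter,
                aop_pct=round(100.0 * inter / len(aop_genes)),
                best_cluster_jaccard=best_ji,
                n_cluster_pairs_above_threshold=n_similar,
            )
        )
    return pd.DataFrame(rows)


def consensus_network(
    hetnet: HeterogeneousNetwork,
    candidates: NovelCandidateSet,
    selected_go_groups: Sequence[GOGroup],
    aop_genes: set[str],
    drug_targets: set[str],
    disease_genes: set[str],
    annotations: AnnotationDB | None = None,
    rng_seed: int = 0,
) -> nx.Graph:
    """Build the consensus mechanism network.

    For every candidate gene, all hop-count shortest paths on the
    protein layer to each drug target and disease gene are enumerated;
    paths through at least one benchmark (AOP) gene are kept.  A
    candidate none of whose paths pass a benchmark gene contributes one
    uniformly random shortest path instead (seeded).  Process nodes are
    attached when their annotated genes overlap both the recovered path
    genes and the candidate-or-benchmark genes.  Node roles
    {candidate, aop, target, disease_gene, linker, process} are assigned
    with that priority.
    """
    rng = np.random.default_rng(rng_seed)
    protein_nodes = hetnet.nodes_of_type("protein")
    layer = hetnet.graph.subgraph(protein_nodes)
    seeds = sorted((set(drug_targets) | set(disease_genes)) & protein_nodes)
    missing = (set(candidates.genes) | set(drug_targets) | set(disease_genes)) - protein_nodes
    if missing:
        logger.warning("consensus_network: %d named genes absent from the protein layer", len(missing))

    out = nx.Graph()
    kept_path_genes: set[str] = set()

    def add_path(path):
        for n in path:
            if not out.has_node(n):
                out.add_node(n, type="protein")
        for a, b in zip(path, path[1:]):
            out.add_edge(a, b, confidence=layer[a][b]["confidence"])
        kept_path_genes.update(path)

    for cand in sorted(set(candidates.genes) & protein_nodes):
        kept_any = False
        fallback: list[list[str]] = []
        for s in seeds:
            if s == cand or not nx.has_path(layer, cand, s):
                continue
            for path in nx.all_shortest_paths(layer, cand, s):
                if set(path) & aop_genes:
                    add_path(path)
                    kept_any = True
                else:
                    fallback.append(path)
        if not kept_any:
            if fallback:
                fallback.sort()
                add_path(fallback[int(rng.integers(len(fallback)))])
            else:
                logger.warning("candidate %r disconnected from both seed sets, dropped", cand)

    interesting = set(candidates.genes) | set(aop_genes)
    for group in selected_go_groups:
        for term in sorted(group.terms):
            genes = (
                set(annotations.genes(term)) if annotations is not None
                else {n for n in hetnet.graph.neighbors(term)} if term in hetnet.graph
                else set()
            )
            path_hits = genes & kept_path_genes
            if path_hits and (genes & interesting):
                out.add_node(term, type="biological_process", role="process")
                for g in sorted(path_hits & set(out.nodes())):
                    out.add_edge(term, g, confidence=0.4)

    for n in out.nodes():
        if out.nodes[n].get("type") != "protein":
            continue
        if n in candidates.genes:
            role = "candidate"
        elif n in aop_genes:
            role = "aop"
        elif n in drug_targets:
            role = "target"
        elif n in disease_genes:
            role = "disease_gene"
        else:
            role = "linker"
        out.nodes[n]["role"] = role
    return out
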