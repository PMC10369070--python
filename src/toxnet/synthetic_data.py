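"""Synthetic study systems with planted ground truth.

Generates (i) a scale-free confidence-weighted interactome, (ii) seed
gene sets for a drug (targets) and an adverse outcome (disease genes),
(iii) a planted *mechanism* gene set that bridges the two and is the
recovery target for every downstream strategy, (iv) an annotation DAG
whose leaf terms annotate the planted genes, and (v) a heterogeneous
network wiring drug, disease and process nodes onto the interactome.

Design of the planted signal
----------------------------
Disease genes are drawn as a snowball (network-local) sample, emulating
the disease-module hypothesis that community-based strategies rely on;
drug targets are drawn uniformly, emulating the scattered placement of
real target sets.  Each mechanism gene is bridged by added edges to two
targets and two disease genes, so that it lies on target↔disease
shortest paths without ever deleting edges (the degree distribution is
preserved up to the added bridges).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import netio
from .enrichment import AnnotationDB
from .errors import ValidationError
from .graphs import (
    DEFAULT_PROCESS_CONFIDENCE,
    HeterogeneousNetwork,
    WeightedInteractome,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario",
    "generate_interactome",
    "plant_mechanism",
    "generate_annotation_dag",
    "build_hetnet_from_scenario",
    "default_scenario",
    "write_scenario",
    "DRUG_NODE",
    "DISEASE_NODE",
]

DRUG_NODE = "DRUG:VPX"
DISEASE_NODE = "DIS:STEATOSIS"

# Default scenario scale: large enough for community structure, small
# enough for brute-force oracles.
DEFAULT_N_PROTEINS = 800
DEFAULT_MEAN_DEGREE = 4.0
DEFAULT_N_PROCESSES = 40
DEFAULT_N_TARGETS = 15
DEFAULT_N_DISEASE = 60
DEFAULT_N_MECHANISM = 12
DEFAULT_N_BENCHMARK_DISEASE = 16
DEFAULT_N_BENCHMARK_TARGETS = 4
#: Beta parameters for protein-edge confidences: high-confidence-skewed,
#: like curated interaction scores, but non-degenerate so that weighting
#: matters.
DEFAULT_CONFIDENCE_DIST = (8.0, 2.0)
BRIDGES_PER_MECHANISM = 2  # bridges to targets and to disease genes, each


@dataclass
class SyntheticScenario:
    """A complete synthetic study system with recorded ground truth."""

    interactome: WeightedInteractome
    drug_targets: set[str]
    disease_genes: set[str]
    planted_mechanism: set[str]
    annotations: AnnotationDB | None = None
    hetnet: HeterogeneousNetwork | None = None
    benchmark_genes: set[str] = field(default_factory=set)
    disease_concepts: dict[str, set[str]] = field(default_factory=dict)
    planted_term: str | None = None
    rng_seed: int = 0

    def __post_init__(self):
        overlap = self.planted_mechanism & (self.drug_targets | self.disease_genes)
        if overlap:
            raise ValidationError(
                f"planted mechanism genes must be novel, found overlap {sorted(overlap)[:5]}"
            )

    @property
    def seed_genes(self) -> set[str]:
        return self.drug_targets | self.disease_genes


def _beta_confidence(rng: np.random.Generator, ab: tuple[float, float], size: int) -> np.ndarray:
    a, b = ab
    c = rng.beta(a, b, size=size)
    return np.clip(c, 1e-6, 1.0)


def generate_interactome(
    n_nodes: int = DEFAULT_N_PROTEINS,
    mean_degree: float = DEFAULT_MEAN_DEGREE,
    confidence_dist: tuple[float, float] = DEFAULT_CONFIDENCE_DIST,
    rng_seed: int = 0,
) -> WeightedInteractome:
    """Scale-free weighted interactome via preferential attachment.

    Edge confidences are Beta(alpha, beta) draws; the graph is connected
    by construction (preferential attachment on a connected seed core).
    """
    if n_nodes < 10:
        raise ValidationError("n_nodes must be ≥ 10")
    if mean_degree < 2:
        raise ValidationError("mean_degree must be ≥ 2")
    m = max(1, int(round(mean_degree / 2)))
    if m >= n_nodes:
        raise ValidationError("mean_degree too large for n_nodes")
    rng = np.random.default_rng(rng_seed)
    ba_seed = int(rng.integers(2**31 - 1))
    g = nx.barabasi_albert_graph(n_nodes, m, seed=ba_seed)
    g = nx.relabel_nodes(g, {i: f"G{i:04d}" for i in g.nodes()})
    conf = _beta_confidence(rng, confidence_dist, g.number_of_edges())
    for (a, b), c in zip(sorted(g.edges()), conf):
        g[a][b]["confidence"] = float(c)
    # preferential attachment yields a connected graph; guard anyway
    if not nx.is_connected(g):  # pragma: no cover - BA graphs are connected
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        anchor = min(comps[0])
        for comp in comps[1:]:
            g.add_edge(anchor, min(comp), confidence=float(_beta_confidence(rng, confidence_dist, 1)[0]))
    return WeightedInteractome(g)


def _snowball_sample(g: nx.Graph, size: int, rng: np.random.Generator) -> set[str]:
    """Network-local sample: grow a set from a random start by repeatedly
    adding a random neighbour of the current frontier."""
    nodes = sorted(g.nodes())
    start = nodes[int(rng.integers(len(nodes)))]
    sample = {start}
    frontier = sorted(set(g.neighbors(start)))
    while len(sample) < size:
        if not frontier:
            candidates = sorted(set(nodes) - sample)
            frontier = [candidates[int(rng.integers(len(candidates)))]]
        pick = frontier[int(rng.integers(len(frontier)))]
        sample.add(pick)
        frontier = sorted((set(frontier) | set(g.neighbors(pick))) - sample)
    return sample


def plant_mechanism(
    interactome: WeightedInteractome,
    n_targets: int = DEFAULT_N_TARGETS,
    n_disease: int = DEFAULT_N_DISEASE,
    n_mechanism: int = DEFAULT_N_MECHANISM,
    rng_seed: int = 0,
    confidence_dist: tuple[float, float] = DEFAULT_CONFIDENCE_DIST,
    max_retries: int = 50,
) -> SyntheticScenario:
    """Select disjoint target/disease/mechanism sets and bridge them.

    Each mechanism gene receives added edges to ``BRIDGES_PER_MECHANISM``
    targets and disease genes chosen so that at least one target–disease
    pair is non-adjacent, putting the mechanism gene on a length-2
    shortest path between them.  Edges are only ever added, never
    deleted.
    """
    g = interactome.graph.copy()
    n_nodes = g.number_of_nodes()
    if n_targets + n_disease + n_mechanism > n_nodes / 2:
        raise ValidationError("seed and mechanism sets must not exceed half the node universe")
    rng = np.random.default_rng(rng_seed)
    nodes = sorted(g.nodes())

    disease = _snowball_sample(g, n_disease, rng)
    remaining = sorted(set(nodes) - disease)
    targets = {remaining[i] for i in rng.choice(len(remaining), size=n_targets, replace=False)}
    remaining = sorted(set(remaining) - targets)
    mechanism = {remaining[i] for i in rng.choice(len(remaining), size=n_mechanism, replace=False)}

    t_sorted, d_sorted = sorted(targets), sorted(disease)
    for m in sorted(mechanism):
        ok = False
        for _ in range(max_retries):
            ts = [t_sorted[i] for i in rng.choice(len(t_sorted), size=BRIDGES_PER_MECHANISM, replace=False)]
            ds = [d_sorted[i] for i in rng.choice(len(d_sorted), size=BRIDGES_PER_MECHANISM, replace=False)]
            if any(not g.has_edge(t, d) for t in ts for d in ds):
                for other in ts + ds:
                    if not g.has_edge(m, other):
                        g.add_edge(
                            m, other,
                            confidence=float(_beta_confidence(rng, confidence_dist, 1)[0]),
                        )
                ok = True
                break
        if not ok:
            raise ValidationError(f"could not bridge mechanism gene {m!r} after {max_retries} retries")

    return SyntheticScenario(
        interactome=WeightedInteractome(g),
        drug_targets=targets,
        disease_genes=disease,
        planted_mechanism=mechanism,
        rng_seed=rng_seed,
    )


def generate_annotation_dag(
    n_terms: int = DEFAULT_N_PROCESSES,
    branching: float = 3.0,
    genes: set[str] | None = None,
    terms_per_gene: tuple[int, int] = (1, 3),
    rng_seed: int = 0,
    enriched_set: set[str] | None = None,
) -> tuple[AnnotationDB, str | None]:
    """Random rooted term DAG with leaf-level gene annotations.

    Built as a random tree (each new term attaches to a uniformly chosen
    earlier term, biased toward ``branching`` children per node) plus
    occasional extra parents to make it a genuine DAG.  Genes are
    annotated to 1–3 random leaves and propagated to ancestors by the
    true-path rule.  When ``enriched_set`` is given, one dedicated leaf
    term annotates exactly those genes (plus a few decoys), so the term
    is enriched in that set by construction.  Returns the database and
    the enriched term's id.
    """
    if n_terms < 3:
        raise ValidationError("n_terms must be ≥ 3")
    rng = np.random.default_rng(rng_seed)
    terms = [f"T:{i:04d}" for i in range(n_terms)]
    root = terms[0]
    pairs: list[tuple[str, str]] = []
    children: dict[str, int] = {t: 0 for t in terms}
    for i in range(1, n_terms):
        # prefer parents with open slots to keep branching ~ requested
        open_parents = [t for t in terms[:i] if children[t] < branching] or terms[:i]
        parent = open_parents[int(rng.integers(len(open_parents)))]
        pairs.append((terms[i], parent))
        children[parent] += 1
        if i > 2 and rng.random() < 0.15:  # extra parent: DAG, not tree
            alt = terms[int(rng.integers(i))]
            if alt != parent and (terms[i], alt) not in pairs:
                pairs.append((terms[i], alt))

    leaf_terms = sorted(set(terms) - {p for _, p in pairs})
    term_genes: dict[str, set[str]] = {t: set() for t in terms}
    genes = set(genes or ())
    enriched_term = None
    if enriched_set:
        # deepest leaf hosts the planted signal, plus a few decoy genes
        enriched_term = leaf_terms[int(rng.integers(len(leaf_terms)))]
        decoy_pool = sorted(genes - set(enriched_set))
        n_decoys = min(3, len(decoy_pool))
        decoys = (
            {decoy_pool[i] for i in rng.choice(len(decoy_pool), size=n_decoys, replace=False)}
            if n_decoys else set()
        )
        term_genes[enriched_term] = set(enriched_set) | decoys
    assignable_leaves = [t for t in leaf_terms if t != enriched_term]
    lo, hi = terms_per_gene
    for gene in sorted(genes - set(enriched_set or ())):
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(assignable_leaves))
        for i in rng.choice(len(assignable_leaves), size=k, replace=False):
            term_genes[assignable_leaves[i]].add(gene)

    db = AnnotationDB(term_genes, pairs, {t: f"synthetic process {t}" for t in terms})
    return db, enriched_term


def build_hetnet_from_scenario(
    scenario: SyntheticScenario,
    type_weights: dict[str, float] | None = None,
    rng_seed: int | None = None,
) -> HeterogeneousNetwork:
    """Wire drug, disease and process nodes onto the interactome.

    One drug node connects to every drug target (pChembl-like activity
    scaled by 1/10 as confidence); one disease node connects to every
    disease gene (association-score-like confidence); each process node
    connects to its directly annotated genes and to its DAG parents with
    the fixed process confidence 0.4.
    """
    if scenario.annotations is None:
        raise ValidationError("scenario needs an annotation DAG before building the hetnet")
    rng = np.random.default_rng(scenario.rng_seed if rng_seed is None else rng_seed)
    g = nx.Graph()
    for n in scenario.interactome.sorted_nodes():
        g.add_node(n, type="protein")
    for a, b, data in scenario.interactome.graph.edges(data=True):
        g.add_edge(a, b, confidence=data["confidence"])

    g.add_node(DRUG_NODE, type="drug")
    for t in sorted(scenario.drug_targets):
        pchembl_like = float(np.clip(rng.normal(7.0, 1.5), 1.0, 10.0))
        g.add_edge(DRUG_NODE, t, confidence=pchembl_like / 10.0)
    g.add_node(DISEASE_NODE, type="disease")
    for d in sorted(scenario.disease_genes):
        g.add_edge(DISEASE_NODE, d, confidence=float(rng.uniform(0.3, 1.0)))

    db = scenario.annotations
    for term in db.terms:
        g.add_node(term, type="biological_process")
    for child, parent in db.dag_pairs():
        g.add_edge(child, parent, confidence=DEFAULT_PROCESS_CONFIDENCE)
    for term in db.terms:
        for gene in sorted(db.direct_genes(term)):
            if gene in scenario.interactome:
                g.add_edge(term, gene, confidence=DEFAULT_PROCESS_CONFIDENCE)
    return HeterogeneousNetwork(g, dict(type_weights) if type_weights else {})


def _split_concepts(disease_genes: set[str], n_concepts: int, rng: np.random.Generator) -> dict[str, set[str]]:
    """Partition disease genes into overlapping 'concept' gene sets,
    mimicking several clinical concepts for one adverse outcome."""
    genes = sorted(disease_genes)
    concepts: dict[str, set[str]] = {}
    assignment = rng.integers(n_concepts, size=len(genes))
    for i in range(n_concepts):
        members = {g for g, a in zip(genes, assignment) if a == i}
        # each concept additionally shares a quarter of the full set
        extra = rng.choice(len(genes), size=max(1, len(genes) // 4), replace=False)
        members |= {genes[j] for j in extra}
        concepts[f"concept_{i}"] = members
    return concepts


def default_scenario(rng_seed: int = 0, n_proteins: int = DEFAULT_N_PROTEINS) -> SyntheticScenario:
    """The package's reference study system, fully reproducible from the seed."""
    rng = np.random.default_rng(rng_seed)
    s_inter, s_plant, s_dag, s_het, s_conc, s_bench = (
        int(rng.integers(2**31 - 1)) for _ in range(6)
    )
    # seed-set sizes scale with the interactome so reduced systems stay valid
    f = min(1.0, n_proteins / DEFAULT_N_PROTEINS)
    n_targets = max(4, round(DEFAULT_N_TARGETS * f))
    n_disease = max(8, round(DEFAULT_N_DISEASE * f))
    n_mechanism = max(3, round(DEFAULT_N_MECHANISM * f))
    interactome = generate_interactome(n_proteins, DEFAULT_MEAN_DEGREE, rng_seed=s_inter)
    scenario = plant_mechanism(
        interactome,
        n_targets,
        n_disease,
        n_mechanism,
        rng_seed=s_plant,
    )
    scenario.rng_seed = rng_seed
    genes = scenario.interactome.nodes
    scenario.annotations, scenario.planted_term = generate_annotation_dag(
        DEFAULT_N_PROCESSES,
        genes=genes,
        rng_seed=s_dag,
        enriched_set=scenario.planted_mechanism,
    )
    scenario.hetnet = build_hetnet_from_scenario(scenario, rng_seed=s_het)
    crng = np.random.default_rng(s_conc)
    scenario.disease_concepts = _split_concepts(scenario.disease_genes, 3, crng)
    brng = np.random.default_rng(s_bench)
    d_sorted, t_sorted = sorted(scenario.disease_genes), sorted(scenario.drug_targets)
    n_bench_d = min(DEFAULT_N_BENCHMARK_DISEASE, max(2, round(DEFAULT_N_BENCHMARK_DISEASE * f)))
    n_bench_t = min(DEFAULT_N_BENCHMARK_TARGETS, max(1, round(DEFAULT_N_BENCHMARK_TARGETS * f)))
    scenario.benchmark_genes = {
        d_sorted[i] for i in brng.choice(len(d_sorted), size=n_bench_d, replace=False)
    } | {
        t_sorted[i] for i in brng.choice(len(t_sorted), size=n_bench_t, replace=False)
    }
    return scenario


def write_scenario(scenario: SyntheticScenario, out_dir) -> dict[str, str]:
    """Serialize every scenario artifact as plain text; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    netio.write_edge_list(scenario.interactome.to_edge_records(), out / "interactome.tsv")
    files["interactome"] = "interactome.tsv"
    for name, genes in (
        ("drug_targets", scenario.drug_targets),
        ("disease_genes", scenario.disease_genes),
        ("planted_mechanism", scenario.planted_mechanism),
        ("benchmark_genes", scenario.benchmark_genes),
    ):
        netio.write_gene_list(genes, out / f"{name}.txt")
        files[name] = f"{name}.txt"
    if scenario.annotations is not None:
        netio.write_gmt(scenario.annotations.to_gmt_records(), out / "annotations.gmt")
        netio.write_dag_table(scenario.annotations.dag_pairs(), out / "term_dag.tsv")
        files["annotations"] = "annotations.gmt"
        files["term_dag"] = "term_dag.tsv"
    if scenario.disease_concepts:
        netio.write_gmt(
            [
                netio.GeneSetRecord(cid, "synthetic disease concept", tuple(sorted(gs)))
                for cid, gs in sorted(scenario.disease_concepts.items())
            ],
            out / "disease_concepts.gmt",
        )
        files["disease_concepts"] = "disease_concepts.gmt"
    if scenario.hetnet is not None:
        netio.write_node_table(
            {n: scenario.hetnet.node_type(n) for n in scenario.hetnet.sorted_nodes()},
            out / "hetnet_nodes.tsv",
        )
        netio.write_edge_list(
            [
                netio.EdgeRecord(a, b, d["confidence"])
                for a, b, d in sorted(scenario.hetnet.graph.edges(data=True))
            ],
            out / "hetnet_edges.tsv",
        )
        files["hetnet_nodes"] = "hetnet_nodes.tsv"
        files["hetnet_edges"] = "hetnet_edges.tsv"
    truth = {
        "rng_seed": scenario.rng_seed,
        "drug_node": DRUG_NODE,
        "disease_node": DISEASE_NODE,
        "planted_mechanism": sorted(scenario.planted_mechanism),
        "planted_term": scenario.planted_term,
        "n_proteins": len(scenario.interactome),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    files["ground_truth"] = "ground_truth.json"
    return files
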