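"""Functional interpretation stack.

Over-representation of a study gene set against term annotations
arranged in an is_a DAG (classic one-sided hypergeometric and a
topology-aware elim variant), semantic-similarity clustering of
significant terms with a representative term per cluster, and Jaccard
comparison between term clusters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .netio import GeneSetRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationDB",
    "TermCluster",
    "enrich_classic",
    "enrich_elim",
    "filter_significant",
    "semantic_similarity",
    "cluster_terms",
    "filter_clusters_by_size",
    "jaccard",
    "bh_adjust",
    "null_calibration",
]


class AnnotationDB:
    """Term → gene annotations plus the is_a hierarchy.

    Annotations are propagated up the DAG on construction (true-path
    rule), so ``genes(child) ⊆ genes(parent)`` for every is_a pair.
    Information content is corpus-based:
    ``IC(t) = −ln(|genes(t)| / |genes(root)|)``.
    """

    def __init__(
        self,
        term_genes: Mapping[str, Iterable[str]],
        dag_pairs: Iterable[tuple[str, str]],
        term_names: Mapping[str, str] | None = None,
    ):
        self.dag = nx.DiGraph()  # edges child -> parent
        terms = set(term_genes)
        for child, parent in dag_pairs:
            self.dag.add_edge(child, parent)
            terms.update((child, parent))
        self.dag.add_nodes_from(terms)
        if not nx.is_directed_acyclic_graph(self.dag):
            cycle = nx.find_cycle(self.dag)
            raise ValidationError(f"term hierarchy contains a cycle: {cycle}")
        roots = [t for t in self.dag.nodes if self.dag.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValidationError(f"term hierarchy must have a single root, found {sorted(roots)}")
        self.root: str = roots[0]
        self.term_names = dict(term_names or {})

        # true-path propagation: a gene annotated to t annotates every ancestor
        self._genes: dict[str, set[str]] = {t: set() for t in self.dag.nodes}
        for t, genes in term_genes.items():
            self._genes[t].update(genes)
        for t in nx.topological_sort(self.dag):  # children before parents
            for parent in self.dag.successors(t):
                self._genes[parent].update(self._genes[t])
        self._ancestors: dict[str, frozenset[str]] = {
            t: frozenset(nx.descendants(self.dag, t)) for t in self.dag.nodes
        }

    @property
    def terms(self) -> list[str]:
        return sorted(self.dag.nodes)

    def genes(self, term: str) -> frozenset[str]:
        if term not in self._genes:
            raise KeyError(f"unknown term {term!r}")
        return frozenset(self._genes[term])

    def direct_genes(self, term: str) -> frozenset[str]:
        """Genes annotated at ``term`` itself, excluding descendant terms'."""
        below = set()
        for d in nx.ancestors(self.dag, term):  # DAG edges point child->parent
            below.update(self._genes[d])
        return frozenset(self._genes[term] - below)

    def ancestors(self, term: str) -> frozenset[str]:
        """Strict ancestors of ``term`` up to (and including) the root."""
        if term not in self._ancestors:
            raise KeyError(f"unknown term {term!r}")
        return self._ancestors[term]

    def leaves(self) -> list[str]:
        return sorted(t for t in self.dag.nodes if self.dag.in_degree(t) == 0)

    def depth(self, term: str) -> int:
        """Longest child→parent path length from ``term`` to the root."""
        return len(nx.dag_longest_path(self.dag.subgraph({term} | set(self._ancestors[term])))) - 1

    def information_content(self, term: str) -> float:
        n_root = len(self._genes[self.root])
        n = len(self.genes(term))
        if n == 0 or n_root == 0:
            return math.inf  # un-annotated term: maximally specific
        return -math.log(n / n_root)

    def to_gmt_records(self, direct_only: bool = True) -> list[GeneSetRecord]:
        out = []
        for t in self.terms:
            members = sorted(self.direct_genes(t) if direct_only else self.genes(t))
            if members:
                out.append(GeneSetRecord(t, self.term_names.get(t, t), tuple(members)))
        return out

    def dag_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.dag.edges())


@dataclass(frozen=True)
class TermCluster:
    """A semantic cluster of enriched terms, labelled by its most
    significant member (the representative)."""

    representative: str
    members: frozenset[str]
    method_name: str = ""

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValidationError("cluster representative must be a member")


def _enrich_frame(rows: list[dict], method: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["term", "name", "study_count", "pop_count", "p_value"])
    df["method"] = method
    if len(df):
        df["p_bh"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    else:
        df["p_bh"] = pd.Series(dtype=float)
    return df


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, p[i] * m / (rank_from_top + 1))
        adj[i] = running
    return adj


def _check_study(study: set[str], background: set[str]):
    if not study:
        raise ValidationError("study gene set is empty")
    extra = study - background
    if extra:
        raise ValidationError(
            f"{len(extra)} study genes missing from the background, e.g. {sorted(extra)[:3]}"
        )


def enrich_classic(
    study: set[str],
    background: set[str],
    annotations: AnnotationDB,
    min_annotated: int = 5,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term.

    Terms with fewer than ``min_annotated`` background-annotated genes
    are excluded from testing.
    """
    study, background = set(study), set(background)
    _check_study(study, background)
    N, n = len(background), len(study)
    rows = []
    for term in annotations.terms:
        pop = annotations.genes(term) & background
        K = len(pop)
        if K < min_annotated:
            continue
        k = len(pop & study)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            dict(term=term, name=annotations.term_names.get(term, term),
                 study_count=k, pop_count=K, p_value=min(p, 1.0))
        )
    return _enrich_frame(rows, "classic")


def enrich_elim(
    study: set[str],
    background: set[str],
    annotations: AnnotationDB,
    elim_threshold: float = 0.01,
    min_annotated: int = 5,
) -> pd.DataFrame:
    """Topology-aware enrichment: the elim variant.

    Terms are processed bottom-up (deepest first).  Whenever a term is
    significant at ``elim_threshold``, its annotated study genes are
    removed from all its ancestors before those ancestors are tested,
    so generic parents are not dragged along by specific children.
    With ``elim_threshold=0`` no elimination ever fires and the result
    equals the classic test.
    """
    study, background = set(study), set(background)
    _check_study(study, background)
    N, n = len(background), len(study)
    order = sorted(
        annotations.terms, key=lambda t: (-annotations.depth(t), t)
    )
    removed: dict[str, set[str]] = {t: set() for t in annotations.terms}
    rows = []
    for term in order:
        pop = annotations.genes(term) & background
        K = len(pop)
        if K < min_annotated:
            continue
        hit = (pop & study) - removed[term]
        k = len(hit)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            dict(term=term, name=annotations.term_names.get(term, term),
                 study_count=k, pop_count=K, p_value=min(p, 1.0))
        )
        if p < elim_threshold:
            eliminate = annotations.genes(term) & study
            for anc in annotations.ancestors(term):
                removed[anc] |= eliminate
    return _enrich_frame(rows, "elim")


def filter_significant(table: pd.DataFrame, p_threshold: float = 0.01) -> list[str]:
    """Terms with p strictly below the threshold (boundary excluded)."""
    if len(table) == 0:
        return []
    keep = table[table["p_value"] < p_threshold]
    return list(keep.sort_values(["p_value", "term"], kind="stable")["term"])


def semantic_similarity(term_a: str, term_b: str, annotations: AnnotationDB) -> float:
    """Lin similarity: 2·IC(MICA) / (IC(a) + IC(b)), in [0, 1].

    The most informative common ancestor (MICA) search includes the
    terms themselves.  The root has IC 0, so sim(root, t) = 0; a term
    compared with itself scores 1.
    """
    for t in (term_a, term_b):
        if t not in annotations.dag:
            raise KeyError(f"unknown term {t!r}")
    if term_a == term_b:
        return 0.0 if term_a == annotations.root else 1.0
    common = ({term_a} | annotations.ancestors(term_a)) & (
        {term_b} | annotations.ancestors(term_b)
    )
    ic_a, ic_b = annotations.information_content(term_a), annotations.information_content(term_b)
    ic_mica = max((annotations.information_content(t) for t in common), default=0.0)
    if not math.isfinite(ic_mica):
        ic_mica = max(ic for ic in (ic_a, ic_b, 0.0) if math.isfinite(ic))
    denom = ic_a + ic_b
    if denom == 0 or not math.isfinite(denom):
        return 0.0
    return float(min(1.0, 2.0 * ic_mica / denom))


def cluster_terms(
    significant_terms: Sequence[str],
    table: pd.DataFrame,
    annotations: AnnotationDB,
    sim_threshold: float = 0.7,
    method_name: str = "",
) -> list[TermCluster]:
    """Greedy semantic clustering of significant terms.

    Terms are visited by ascending p (ties: lexicographic id); each
    joins the first existing cluster whose representative is at least
    ``sim_threshold`` similar, otherwise it founds a new cluster.  The
    representative is the lowest-p member, which by construction is the
    founder.
    """
    pvals = dict(zip(table["term"], table["p_value"]))
    ordered = sorted(significant_terms, key=lambda t: (pvals.get(t, 1.0), t))
    reps: list[str] = []
    members: list[list[str]] = []
    for term in ordered:
        for i, rep in enumerate(reps):
            if semantic_similarity(term, rep, annotations) >= sim_threshold:
                members[i].append(term)
                break
        else:
            reps.append(term)
            members.append([term])
    out = []
    for rep, mem in zip(reps, members):
        best = min(mem, key=lambda t: (pvals.get(t, 1.0), t))
        out.append(TermCluster(representative=best, members=frozenset(mem), method_name=method_name))
    return out


def filter_clusters_by_size(clusters: Iterable[TermCluster], min_terms: int = 3) -> list[TermCluster]:
    """Keep clusters with at least ``min_terms`` members (inclusive)."""
    return [c for c in clusters if len(c.members) >= min_terms]


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard index |A∩B| / |A∪B|; two empty sets give 0 with a warning."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        logger.warning("jaccard of two empty sets is defined as 0")
        return 0.0
    return len(a & b) / len(union)


def null_calibration(
    annotations: AnnotationDB,
    background: set[str],
    study_size: int,
    n_sims: int = 1000,
    p_threshold: float = 0.01,
    min_annotated: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of (term, simulation) tests significant under the null.

    Draws ``n_sims`` random study sets from the background and returns
    the overall fraction of term tests with p < ``p_threshold``.  For a
    calibrated test this stays at or below the nominal level.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    bg = sorted(background)
    N = len(bg)
    idx = {g: i for i, g in enumerate(bg)}
    term_masks = []
    for term in annotations.terms:
        pop = annotations.genes(term) & background
        if len(pop) < min_annotated:
            continue
        mask = np.zeros(N, dtype=bool)
        mask[[idx[g] for g in pop]] = True
        term_masks.append(mask)
    if not term_masks:
        raise ValidationError("no testable terms for calibration")
    masks = np.array(term_masks)  # (T, N)
    K = masks.sum(axis=1)
    n_sig = 0
    for _ in range(n_sims):
        pick = rng.choice(N, size=study_size, replace=False)
        study_mask = np.zeros(N, dtype=bool)
        study_mask[pick] = True
        k = (masks & study_mask).sum(axis=1)
        p = hypergeom.sf(k - 1, N, K, study_size)
        n_sig += int((p < p_threshold).sum())
    return n_sig / (n_sims * len(masks))
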