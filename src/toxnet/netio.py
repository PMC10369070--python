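"""Readers and writers for every external format the pipeline touches.

All identifiers are opaque strings; no ID mapping is performed.  Readers
never silently drop rows: collapsed or skipped records are counted and
logged through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeRecord",
    "GeneSetRecord",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_dag_table",
    "write_dag_table",
    "read_node_table",
    "write_node_table",
    "write_network_export",
    "read_graphml",
]


@dataclass(frozen=True)
class EdgeRecord:
    """One confidence-weighted interaction.

    ``confidence`` must lie in (0, 1] and self-interactions are rejected
    (self-interacting proteins are excluded from the scaffold by design).
    """

    node_a: str
    node_b: str
    confidence: float

    def __post_init__(self):
        if self.node_a == self.node_b:
            raise ValidationError(f"self-loop on {self.node_a!r} rejected")
        if not (0.0 < self.confidence <= 1.0):
            raise ValidationError(
                f"confidence {self.confidence} for ({self.node_a}, {self.node_b}) "
                "outside (0, 1]"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Canonical unordered key for duplicate collapsing."""
        return (self.node_a, self.node_b) if self.node_a <= self.node_b else (self.node_b, self.node_a)


@dataclass(frozen=True)
class GeneSetRecord:
    """A named gene set (GMT row); members are de-duplicated, order kept."""

    set_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


def _dedup(items) -> tuple[str, ...]:
    seen, out = set(), []
    for x in items:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return tuple(out)


def read_edge_list(
    path,
    directed: bool = False,
    columns: tuple[int, int, int] = (0, 1, 2),
    skip_header: bool = False,
) -> list[EdgeRecord]:
    """Read a TSV edge list into validated :class:`EdgeRecord` objects.

    Duplicate undirected edges are collapsed keeping the maximum
    confidence.  ``columns`` maps (node_a, node_b, confidence) onto
    zero-based column indices so arbitrary interactome dialects can be
    read without guessing column names.
    """
    ia, ib, ic = columns
    need = max(columns) + 1
    best: dict[tuple[str, str], EdgeRecord] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < need:
                raise ParseError(
                    f"expected ≥{need} tab-separated columns, got {len(parts)}",
                    path=path, line=lineno,
                )
            try:
                conf = float(parts[ic])
            except ValueError as exc:
                raise ParseError(
                    f"confidence {parts[ic]!r} is not a number", path=path, line=lineno
                ) from exc
            rec = EdgeRecord(parts[ia].strip(), parts[ib].strip(), conf)
            key = (rec.node_a, rec.node_b) if directed else rec.key
            if key in best:
                n_dup += 1
                if rec.confidence > best[key].confidence:
                    best[key] = rec
            else:
                best[key] = rec
    if n_dup:
        logger.info("read_edge_list(%s): collapsed %d duplicate edges (kept max confidence)", path, n_dup)
    return list(best.values())


def write_edge_list(records, path) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: r.key):
            fh.write(f"{r.node_a}\t{r.node_b}\t{r.confidence:.6g}\n")


def read_gmt(path) -> list[GeneSetRecord]:
    """Read a GMT file (set_id TAB description TAB member...)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"GMT line needs ≥3 fields, got {len(parts)}", path=path, line=lineno
                )
            members = _dedup(p.strip() for p in parts[2:] if p.strip())
            out.append(GeneSetRecord(parts[0].strip(), parts[1].strip(), members))
    return out


def write_gmt(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join((r.set_id, r.description) + r.members) + "\n")


def read_gene_list(path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            genes.add(s)
    if not genes:
        logger.warning("read_gene_list(%s): no identifiers found", path)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_dag_table(path) -> list[tuple[str, str]]:
    """Read two-column child→parent TSV pairs (acyclicity checked later)."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError("DAG row needs 2 columns", path=path, line=lineno)
            if len(parts) > 2:
                logger.warning("read_dag_table(%s): line %d has extra columns, ignored", path, lineno)
            pairs.append((parts[0].strip(), parts[1].strip()))
    return pairs


def write_dag_table(pairs, path) -> None:
    with open(path, "w") as fh:
        for child, parent in pairs:
            fh.write(f"{child}\t{parent}\n")


def read_node_table(path, skip_header: bool = False) -> dict[str, str]:
    """Read a two-column node_id TAB node_type table."""
    from .graphs import NODE_TYPES

    types: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("node table row needs 2 columns", path=path, line=lineno)
            nid, ntype = parts[0].strip(), parts[1].strip()
            if ntype not in NODE_TYPES:
                raise ValidationError(f"{path}:{lineno}: unknown node type {ntype!r}")
            if nid in types:
                raise ValidationError(f"{path}:{lineno}: duplicate node id {nid!r}")
            types[nid] = ntype
    return types


def write_node_table(types: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for nid in sorted(types):
            fh.write(f"{nid}\t{types[nid]}\n")


_EXPORT_FORMATS = ("graphml", "sif", "tsv")


def write_network_export(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Export a typed, confidence-weighted graph for standard viewers.

    Node ``type`` (and ``role`` if present) and edge ``confidence`` are
    preserved as attributes for graphml/tsv; SIF keeps topology only.
    """
    if format not in _EXPORT_FORMATS:
        raise ValueError(f"unknown export format {format!r}; choose from {_EXPORT_FORMATS}")
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "sif":
        with open(path, "w") as fh:
            seen = set()
            for a, b in sorted(map(tuple, map(sorted, graph.edges()))):
                fh.write(f"{a}\tpp\t{b}\n")
                seen.update((a, b))
            for n in sorted(set(graph.nodes()) - seen):
                fh.write(f"{n}\n")
    else:  # tsv
        with open(path, "w") as fh:
            fh.write("node_a\ttype_a\tnode_b\ttype_b\tconfidence\n")
            for a, b, data in sorted(graph.edges(data=True)):
                fh.write(
                    f"{a}\t{graph.nodes[a].get('type', '')}\t"
                    f"{b}\t{graph.nodes[b].get('type', '')}\t"
                    f"{data.get('confidence', '')}\n"
                )


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
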