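"""Biased random walk on the heterogeneous network.

The walker at node i jumps to neighbour j of type t with raw propensity
w_t · u_ij / n_t, where w_t is the scalar weight of type t, u_ij the
edge confidence and n_t the number of i's neighbours of type t; rows
are then normalized to distributions (the raw propensities alone need
not sum to one).  Restarting walks from the drug and the disease node
yield diffusion profiles — stationary visitation-frequency vectors —
whose elementwise product is the Treatment Importance (TI) used to rank
proteins and processes by joint relevance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ConvergenceError, ValidationError
from .graphs import HeterogeneousNetwork, MethodResult

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix",
    "DiffusionProfile",
    "build_transition_matrix",
    "diffusion_profile",
    "treatment_importance",
    "top_k_by_ti",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic biased transition matrix over a fixed node order."""

    matrix: sp.csr_matrix
    nodes: list[str]
    node_types: dict[str, str]
    #: rows with no neighbours; handled as pure restart during walks
    dangling: frozenset[str] = frozenset()

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}


def raw_transition_entries(hetnet: HeterogeneousNetwork, node: str) -> dict[str, float]:
    """Unnormalized propensities w_t · u_ij / n_t for one node's row."""
    g = hetnet.graph
    nbrs = sorted(g.neighbors(node))
    n_by_type: dict[str, int] = {}
    for j in nbrs:
        t = hetnet.node_type(j)
        n_by_type[t] = n_by_type.get(t, 0) + 1
    out = {}
    for j in nbrs:
        t = hetnet.node_type(j)
        out[j] = hetnet.type_weights[t] * g[node][j]["confidence"] / n_by_type[t]
    return out


def build_transition_matrix(hetnet: HeterogeneousNetwork) -> TransitionMatrix:
    """Assemble the biased transition matrix, row-normalized."""
    nodes = hetnet.sorted_nodes()
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    dangling = []
    for n in nodes:
        entries = raw_transition_entries(hetnet, n)
        if not entries:
            dangling.append(n)
            continue
        total = sum(entries.values())
        for j, v in entries.items():
            rows.append(idx[n])
            cols.append(idx[j])
            vals.append(v / total)
    if dangling:
        logger.warning("%d isolated nodes have no transitions (restart-only rows)", len(dangling))
    M = sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    return TransitionMatrix(
        matrix=M,
        nodes=nodes,
        node_types={n: hetnet.node_type(n) for n in nodes},
        dangling=frozenset(dangling),
    )


@dataclass
class DiffusionProfile:
    """Stationary visitation-frequency distribution of a restarting walk."""

    start_node: str
    visitation: dict[str, float]
    restart: float

    def __post_init__(self):
        total = sum(self.visitation.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"visitation frequencies sum to {total}, expected 1")


def diffusion_profile(
    tm: TransitionMatrix,
    start_node: str,
    restart: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> DiffusionProfile:
    """Power-iterate v ← r·e_start + (1−r)·Mᵀv to its fixed point.

    Dangling rows restart deterministically, so total visitation mass
    is conserved at every iteration.
    """
    if start_node not in tm.index:
        raise ValidationError(f"start node {start_node!r} not in the network")
    if not (0.0 < restart < 1.0):
        raise ValidationError(f"restart must be in (0, 1), got {restart}")
    n = len(tm.nodes)
    i0 = tm.index[start_node]
    e = np.zeros(n)
    e[i0] = 1.0
    dang = np.array([tm.index[d] for d in tm.dangling], dtype=int)
    MT = tm.matrix.T.tocsr()
    v = e.copy()
    for _ in range(max_iter):
        dangling_mass = float(v[dang].sum()) if len(dang) else 0.0
        v_new = restart * e + (1.0 - restart) * (MT @ v + dangling_mass * e)
        delta = float(np.abs(v_new - v).sum())
        v = v_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"diffusion did not converge in {max_iter} iterations", residual=delta)
    v = v / v.sum()  # remove residual numerical drift
    return DiffusionProfile(
        start_node=start_node,
        visitation=dict(zip(tm.nodes, map(float, v))),
        restart=restart,
    )


def treatment_importance(
    drug_profile: DiffusionProfile,
    disease_profile: DiffusionProfile,
    node_types: dict[str, str] | None = None,
    keep_types: tuple[str, ...] = ("protein", "biological_process"),
) -> dict[str, float]:
    """TI(node) = drug visitation × disease visitation, per node.

    Symmetric in the two profiles; optionally restricted to the
    requested node types when ``node_types`` is supplied.
    """
    if set(drug_profile.visitation) != set(disease_profile.visitation):
        raise ValidationError("profiles are defined over different node universes")
    ti = {}
    for n, v in drug_profile.visitation.items():
        if node_types is not None and node_types.get(n) not in keep_types:
            continue
        ti[n] = v * disease_profile.visitation[n]
    return ti


def top_k_by_ti(
    ti: dict[str, float],
    k: int = 1000,
    node_types: dict[str, str] | None = None,
    node_type_filter: str | None = "protein",
    method_name: str = "diffusion",
) -> MethodResult:
    """Top-k nodes by TI, ties at the boundary broken by node id.

    Only nodes with TI > 0 count; if fewer than k exist they are all
    returned with a warning.
    """
    if k < 1:
        raise ValidationError("k must be ≥ 1")
    pool = {
        n: v
        for n, v in ti.items()
        if v > 0
        and (node_type_filter is None or node_types is None or node_types.get(n) == node_type_filter)
    }
    ranked = sorted(pool, key=lambda n: (-pool[n], n))
    if len(ranked) < k:
        logger.warning("top_k_by_ti: only %d nodes with TI > 0 (requested %d)", len(ranked), k)
    chosen = ranked[:k]
    return MethodResult(
        method_name=method_name,
        genes=frozenset(chosen),
        scores={n: pool[n] for n in chosen},
        metadata={"k": k, "n_positive": len(ranked), "node_type_filter": node_type_filter},
    )
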