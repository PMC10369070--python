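"""Seed-based prioritization on the interactome.

Seeds (drug targets ∪ disease genes) get prior 1.0, all other nodes
0.1; a confidence-weighted random walk with restart to the normalized
prior distribution produces steady-state scores, which are min–max
rescaled to [0, 1].  Genes at or above the cutoff (default 0.8,
inclusive) form the method's gene set.  The propagation kernel is
pluggable; RWR is the default realization.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .errors import ConvergenceError, ValidationError
from .graphs import MethodResult, WeightedInteractome

logger = logging.getLogger(__name__)

__all__ = ["make_priors", "propagate", "select_by_threshold"]

SEED_PRIOR = 1.0
NONSEED_PRIOR = 0.1


def make_priors(interactome: WeightedInteractome, seeds: set[str]) -> dict[str, float]:
    """Prior vector: seeds 1.0, everything else 0.1.

    Seeds absent from the graph are dropped with a warning; an empty
    effective seed set is an error.
    """
    nodes = interactome.nodes
    missing = set(seeds) - nodes
    if missing:
        logger.warning("make_priors: %d seeds not in the interactome, dropped", len(missing))
    effective = set(seeds) & nodes
    if not effective:
        raise ValidationError("no seeds present in the interactome")
    return {n: (SEED_PRIOR if n in effective else NONSEED_PRIOR) for n in interactome.sorted_nodes()}


def _column_normalized_adjacency(interactome: WeightedInteractome, nodes: list[str]) -> sp.csr_matrix:
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for a, b, data in interactome.graph.edges(data=True):
        c = data["confidence"]
        rows.extend((idx[a], idx[b]))
        cols.extend((idx[b], idx[a]))
        vals.extend((c, c))
    W = sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    colsum = np.asarray(W.sum(axis=0)).ravel()
    inv = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    return (W @ sp.diags(inv)).tocsr()


def propagate(
    interactome: WeightedInteractome,
    priors: Mapping[str, float],
    restart: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Random walk with restart to the prior distribution.

    Iterates s ← r·p̂ + (1−r)·W·s with p̂ the L1-normalized priors and
    W the confidence-weighted column-normalized adjacency, stopping when
    the L1 change drops below ``tol``.  Scores are then min–max rescaled
    to [0, 1].
    """
    if not (0.0 < restart < 1.0):
        raise ValidationError(f"restart must be in (0, 1), got {restart}")
    nodes = interactome.sorted_nodes()
    if set(priors) != set(nodes):
        raise ValidationError("priors must cover exactly the interactome nodes")
    p = np.array([priors[n] for n in nodes], dtype=float)
    if p.sum() <= 0:
        raise ValidationError("prior mass must be positive")
    p_hat = p / p.sum()
    W = _column_normalized_adjacency(interactome, nodes)

    s = p_hat.copy()
    for _ in range(max_iter):
        s_new = restart * p_hat + (1.0 - restart) * (W @ s)
        delta = float(np.abs(s_new - s).sum())
        s = s_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"propagation did not converge in {max_iter} iterations", residual=delta
        )

    lo, hi = float(s.min()), float(s.max())
    rescaled = np.ones_like(s) if hi == lo else (s - lo) / (hi - lo)
    return dict(zip(nodes, map(float, rescaled)))


def propagate_raw(
    interactome: WeightedInteractome,
    priors: Mapping[str, float],
    restart: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> dict[str, float]:
    """Pre-rescale fixed point of the same iteration (for diagnostics
    and cross-checks against the direct linear solve)."""
    if not (0.0 < restart < 1.0):
        raise ValidationError(f"restart must be in (0, 1), got {restart}")
    nodes = interactome.sorted_nodes()
    p = np.array([priors[n] for n in nodes], dtype=float)
    p_hat = p / p.sum()
    W = _column_normalized_adjacency(interactome, nodes)
    s = p_hat.copy()
    for _ in range(max_iter):
        s_new = restart * p_hat + (1.0 - restart) * (W @ s)
        delta = float(np.abs(s_new - s).sum())
        s = s_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", residual=delta)
    return dict(zip(nodes, map(float, s)))


def select_by_threshold(
    scores: Mapping[str, float], cutoff: float = 0.8, method_name: str = "propagation"
) -> MethodResult:
    """Genes with rescaled score ≥ cutoff (boundary inclusive)."""
    genes = frozenset(n for n, v in scores.items() if v >= cutoff)
    return MethodResult(
        method_name=method_name,
        genes=genes,
        scores={n: scores[n] for n in sorted(genes)},
        metadata={"cutoff": cutoff, "n_scored": len(scores)},
    )
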