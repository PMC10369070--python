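import networkx as nx
import numpy as np
import pytest

from toxnet.enrichment import AnnotationDB
from toxnet.graphs import WeightedInteractome
from toxnet.pipeline import PipelineConfig, run_pipeline
from toxnet.synthetic_data import default_scenario


@pytest.fixture(scope="session")
def scenario0():
    """The default synthetic study system at seed 0 (shared, read-only)."""
    return default_scenario(rng_seed=0)


@pytest.fixture(scope="session")
def pipeline_run0(tmp_path_factory, scenario0):
    """One full end-to-end run at seed 0 (shared across acceptance tests)."""
    out = tmp_path_factory.mktemp("run0")
    cfg = PipelineConfig(rng_seed=0, out_dir=str(out))
    manifest = run_pipeline(cfg, scenario=scenario0)
    return cfg, manifest, out


@pytest.fixture
def path_graph():
    """A–B–C path with distinct confidences."""
    g = nx.Graph()
    g.add_edge("A", "B", confidence=0.9)
    g.add_edge("B", "C", confidence=0.8)
    return WeightedInteractome(g)


@pytest.fixture
def two_node_graph():
    g = nx.Graph()
    g.add_edge("a", "b", confidence=1.0)
    return WeightedInteractome(g)


@pytest.fixture
def chain_db():
    """Three-term chain root→A→B with gene counts 100 / 10 / 10."""
    genes_root = {f"g{i}" for i in range(100)}
    genes_a = {f"g{i}" for i in range(10)}
    return AnnotationDB(
        {"root": genes_root - genes_a, "A": set(), "B": genes_a},
        [("B", "A"), ("A", "root")],
    )


def random_interactome(n, p, rng, ensure_connected=True):
    """Small Erdős–Rényi confidence-weighted test graph."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes()})
    if ensure_connected:
        comps = sorted(nx.connected_components(g), key=lambda c: min(c))
        for a, b in zip(comps, comps[1:]):
            g.add_edge(min(a), min(b))
    for a, b in g.edges():
        g[a][b]["confidence"] = float(rng.uniform(0.05, 1.0))
    return WeightedInteractome(g)
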