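"""End-to-end orchestration: synthetic scenario → four strategies →
enrichment → term clustering → consensus, with a run manifest.

A single global seed fans out to per-stage derived seeds so each stage
is independently reproducible; two runs from the same config produce
identical stage checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import clustering, consensus, diffusion, enrichment, netio, propagation, steiner
from .errors import ValidationError
from .graphs import MethodResult
from .synthetic_data import DISEASE_NODE, DRUG_NODE, SyntheticScenario, default_scenario, write_scenario

logger = logging.getLogger(__name__)

METHOD_ORDER = ("clustering", "propagation", "steiner", "diffusion")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report_tables"]


@dataclass
class PipelineConfig:
    """Validated configuration for one full run."""

    rng_seed: int = 0
    out_dir: str = "toxnet_run"
    n_proteins: int = 800
    skip: tuple[str, ...] = ()
    # per-stage parameter blocks
    clustering: dict = field(default_factory=lambda: {
        "method": "louvain", "resolution": 1.0, "min_size": 5, "p_threshold": 0.05,
        "correction": "bh", "target_rule": "contain",
    })
    propagation: dict = field(default_factory=lambda: {
        "restart": 0.5, "cutoff": 0.8, "tol": 1e-9, "max_iter": 10000,
    })
    steiner: dict = field(default_factory=lambda: {
        "linker_discount": 0.5, "cost_transform": "one_minus_confidence",
    })
    diffusion: dict = field(default_factory=lambda: {
        "restart": 0.5, "top_k_factor": 3,
    })
    enrichment: dict = field(default_factory=lambda: {
        "method": "elim", "p_threshold": 0.01, "min_annotated": 5,
        "sim_threshold": 0.7, "min_cluster_terms": 3,
    })
    consensus: dict = field(default_factory=lambda: {
        "min_support": 2, "jaccard_threshold": 0.4,
    })

    _KNOWN = {
        "rng_seed", "out_dir", "n_proteins", "skip", "clustering", "propagation",
        "steiner", "diffusion", "enrichment", "consensus",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, value in data.items():
            if isinstance(getattr(cfg, key), dict):
                block = dict(getattr(cfg, key))
                bad = set(value) - set(block)
                if bad:
                    raise ValidationError(f"unknown keys in config block {key!r}: {sorted(bad)}")
                block.update(value)
                setattr(cfg, key, block)
            elif key == "skip":
                bad = set(value) - set(METHOD_ORDER)
                if bad:
                    raise ValidationError(f"cannot skip unknown stages: {sorted(bad)}")
                setattr(cfg, key, tuple(value))
            else:
                setattr(cfg, key, value)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self):
        if not (0.0 < self.propagation["restart"] < 1.0):
            raise ValidationError("propagation.restart must be in (0, 1)")
        if not (0.0 < self.diffusion["restart"] < 1.0):
            raise ValidationError("diffusion.restart must be in (0, 1)")
        if set(self.skip) >= set(METHOD_ORDER):
            raise ValidationError("cannot skip every method")

    def content_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # same experiment wherever it is written
        blob = json.dumps(payload, sort_keys=True, default=list).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    rng_seed: int
    stages: dict = field(default_factory=dict)  # stage -> {status, checksums, counts}
    gene_counts: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "rng_seed": self.rng_seed,
                "stages": self.stages,
                "gene_counts": self.gene_counts,
                "timestamps": self.timestamps,
            },
            indent=2, sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksum_dir(d: Path) -> dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(d.iterdir()) if p.is_file()}


def _stage_seed(seed: int, stage_index: int) -> int:
    return (seed + 1009 * (stage_index + 1)) % (2**31 - 1)


def _write_method_result(result: MethodResult, out: Path) -> None:
    with open(out, "w") as fh:
        fh.write("gene\tscore\n")
        scores = result.scores or {}
        for g in sorted(result.genes):
            fh.write(f"{g}\t{scores.get(g, '')}\n")


def run_pipeline(config: PipelineConfig, scenario: SyntheticScenario | None = None) -> RunManifest:
    """Execute every stage in dependency order and write all artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.content_hash(), rng_seed=config.rng_seed)
    t0 = time.time()

    def finish_stage(name, stage_dir: Path, extra=None):
        manifest.stages[name] = {
            "status": "done",
            "checksums": _checksum_dir(stage_dir),
            **(extra or {}),
        }
        manifest.timestamps[name] = round(time.time() - t0, 3)

    # stage 0: synthetic scenario
    synth_dir = out / "synth"
    if scenario is None:
        scenario = default_scenario(rng_seed=config.rng_seed, n_proteins=config.n_proteins)
    write_scenario(scenario, synth_dir)
    finish_stage("synth", synth_dir, {"n_proteins": len(scenario.interactome)})

    interactome = scenario.interactome
    background = interactome.nodes
    results: list[MethodResult] = []
    methods_dir = out / "methods"
    methods_dir.mkdir(exist_ok=True)

    if "clustering" not in config.skip:
        pc = config.clustering
        partition = clustering.detect_communities(
            interactome, method=pc["method"], resolution=pc["resolution"],
            rng_seed=_stage_seed(config.rng_seed, 1),
        )
        selection = clustering.select_clusters(
            partition, scenario.disease_concepts, scenario.drug_targets, background,
            p_threshold=pc["p_threshold"], min_size_exclusive=pc["min_size"],
            correction=pc["correction"], target_rule=pc["target_rule"],
        )
        results.append(clustering.clustering_method_result(selection, partition))
    else:
        manifest.stages["clustering"] = {"status": "skipped"}

    if "propagation" not in config.skip:
        pp = config.propagation
        if not scenario.seed_genes:
            raise ValidationError("propagation requires seed genes")
        priors = propagation.make_priors(interactome, scenario.seed_genes)
        scores = propagation.propagate(
            interactome, priors, restart=pp["restart"], tol=pp["tol"], max_iter=pp["max_iter"]
        )
        results.append(propagation.select_by_threshold(scores, cutoff=pp["cutoff"]))
    else:
        manifest.stages["propagation"] = {"status": "skipped"}

    if "steiner" not in config.skip:
        ps = config.steiner
        cfg = steiner.SteinerConfig(
            seeds=frozenset(scenario.drug_targets),
            preferred_linkers=frozenset(scenario.disease_genes),
            linker_discount=ps["linker_discount"],
            cost_transform=ps["cost_transform"],
        )
        subnet = steiner.steiner_subnetwork(interactome, cfg)
        results.append(steiner.steiner_method_result(subnet))
    else:
        manifest.stages["steiner"] = {"status": "skipped"}

    if "diffusion" not in config.skip:
        pd_ = config.diffusion
        if scenario.hetnet is None:
            raise ValidationError("diffusion requires the heterogeneous network")
        tm = diffusion.build_transition_matrix(scenario.hetnet)
        drug_prof = diffusion.diffusion_profile(tm, DRUG_NODE, restart=pd_["restart"])
        dis_prof = diffusion.diffusion_profile(tm, DISEASE_NODE, restart=pd_["restart"])
        ti = diffusion.treatment_importance(drug_prof, dis_prof)
        k = pd_["top_k_factor"] * len(scenario.planted_mechanism | scenario.seed_genes)
        results.append(
            diffusion.top_k_by_ti(ti, k=k, node_types=tm.node_types, node_type_filter="protein")
        )
    else:
        manifest.stages["diffusion"] = {"status": "skipped"}

    for r in results:
        _write_method_result(r, methods_dir / f"{r.method_name}.tsv")
    finish_stage("methods", methods_dir, {"methods_run": [r.method_name for r in results]})

    # enrichment + term clustering per method
    pe = config.enrichment
    enrich_dir = out / "enrichment"
    enrich_dir.mkdir(exist_ok=True)
    per_method_clusters: dict[str, list[enrichment.TermCluster]] = {}
    enrich_stats = {}
    db = scenario.annotations
    for r in results:
        study = set(r.genes) & background
        if not study:
            per_method_clusters[r.method_name] = []
            enrich_stats[r.method_name] = {"significant_terms": 0, "clusters": 0, "clusters_ge3": 0}
            continue
        fn = enrichment.enrich_elim if pe["method"] == "elim" else enrichment.enrich_classic
        table = fn(study, background, db, min_annotated=pe["min_annotated"])
        sig = enrichment.filter_significant(table, p_threshold=pe["p_threshold"])
        clusters = enrichment.cluster_terms(
            sig, table, db, sim_threshold=pe["sim_threshold"], method_name=r.method_name
        )
        kept = enrichment.filter_clusters_by_size(clusters, min_terms=pe["min_cluster_terms"])
        # keep every cluster for grouping context, but record size-filter stats
        per_method_clusters[r.method_name] = clusters
        enrich_stats[r.method_name] = {
            "significant_terms": len(sig),
            "clusters": len(clusters),
            "clusters_ge3": len(kept),
        }
        table.to_csv(enrich_dir / f"{r.method_name}_terms.tsv", sep="\t", index=False)
    finish_stage("enrichment", enrich_dir, {"stats": enrich_stats})

    # consensus
    pcs = config.consensus
    cons_dir = out / "consensus"
    cons_dir.mkdir(exist_ok=True)
    report = consensus.overlap_report(results)
    cands = consensus.novel_candidates(
        report, scenario.drug_targets, scenario.disease_genes, min_support=pcs["min_support"]
    )
    groups = consensus.group_go_clusters(per_method_clusters, jaccard_threshold=pcs["jaccard_threshold"])
    chosen_groups = consensus.selected_groups(groups)
    bench = consensus.benchmark_against_aop(
        results, scenario.benchmark_genes, per_method_clusters=per_method_clusters
    )
    bench.to_csv(cons_dir / "benchmark.tsv", sep="\t", index=False)
    netio.write_gene_list(cands.genes, cons_dir / "novel_candidates.txt")
    with open(cons_dir / "overlaps.tsv", "w") as fh:
        fh.write("gene\tn_methods\tmethods\n")
        for g in sorted(report.support):
            ms = report.support[g]
            fh.write(f"{g}\t{len(ms)}\t{','.join(sorted(ms))}\n")
    with open(cons_dir / "go_groups.tsv", "w") as fh:
        fh.write("group\tn_clusters\tmethods\trules\trepresentatives\n")
        for i, g in enumerate(groups):
            fh.write(
                f"GRP{i:03d}\t{len(g.clusters)}\t{','.join(sorted(g.methods))}\t"
                f"{','.join(sorted(g.satisfied_rules))}\t"
                f"{','.join(sorted({c.representative for c in g.clusters}))}\n"
            )
    if scenario.hetnet is not None:
        net = consensus.consensus_network(
            scenario.hetnet, cands, chosen_groups, scenario.benchmark_genes,
            scenario.drug_targets, scenario.disease_genes,
            annotations=db, rng_seed=_stage_seed(config.rng_seed, 7),
        )
        netio.write_network_export(net, cons_dir / "consensus_network.graphml", "graphml")
    finish_stage("consensus", cons_dir, {
        "n_candidates": len(cands.genes),
        "n_groups": len(groups),
        "n_selected_groups": len(chosen_groups),
    })

    # Table-2/Table-3 style summaries
    manifest.gene_counts = _gene_count_table(results, scenario, cands, enrich_stats)
    report_tables(manifest, out)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _gene_count_table(results, scenario, cands, enrich_stats) -> dict:
    targets, disease = scenario.drug_targets, scenario.disease_genes
    bench = scenario.benchmark_genes
    rows = {}
    for r in results:
        per_method_cands = {
            g for g in r.genes if g not in targets | disease
        }
        rows[r.method_name] = {
            "total_genes": len(r.genes),
            "targets_recovered": len(r.genes & targets),
            "disease_recovered": len(r.genes & disease),
            "seed_recovered": len(r.genes & (targets | disease)),
            "benchmark_recovered": len(r.genes & bench),
            "new_candidates": len(per_method_cands),
            **enrich_stats.get(r.method_name, {}),
        }
    union = set().union(*(r.genes for r in results)) if results else set()
    rows["totals_unique"] = {
        "total_genes": len(union),
        "targets_recovered": len(union & targets),
        "disease_recovered": len(union & disease),
        "seed_recovered": len(union & (targets | disease)),
        "benchmark_recovered": len(union & bench),
        "new_candidates": len(cands.genes),
    }
    return rows


def report_tables(manifest: RunManifest, out_dir) -> None:
    """Emit the method × metric TSV summary for a completed run."""
    out = Path(out_dir)
    counts = manifest.gene_counts
    cols = [
        "total_genes", "targets_recovered", "disease_recovered",
        "seed_recovered", "benchmark_recovered", "new_candidates",
        "significant_terms", "clusters", "clusters_ge3",
    ]
    with open(out / "summary_genes.tsv", "w") as fh:
        fh.write("method\t" + "\t".join(cols) + "\n")
        for method, row in counts.items():
            fh.write(method + "\t" + "\t".join(str(row.get(c, 0)) for c in cols) + "\n")
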