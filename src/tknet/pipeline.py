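"""End-to-end orchestration: simulate (or load) -> preprocess -> diversity ->
differential -> network -> topology -> null ensemble.

A single global seed fans out to per-stage seeds through a fixed
``numpy.random.SeedSequence`` derivation, so any stage can be re-run in
isolation and a fixed configuration yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import differential, diversity, network, preprocess, simulate, topology
from .config import AnalysisConfig, ConfigError
from .netgraph import TranskingdomNetwork, write_network
from .tables import CountTable, Group, HostTable, SampleMetadata, TaxonomyTable

__all__ = ["PipelineResult", "run_pipeline", "run_all", "stage_seeds", "STAGES"]

log = logging.getLogger("tknet")

STAGES = ("simulate", "preprocess", "diversity", "differential", "network", "topology", "null")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(STAGES, children)}


@dataclass
class PipelineResult:
    config: AnalysisConfig
    study: simulate.StudyData
    common_features: list[str]
    qn_by_exp: dict[int, CountTable]
    host_norm: HostTable
    alpha: dict[int, pd.DataFrame]
    anosim: dict[int, tuple[float, float]]
    pcoa_variance: dict[int, np.ndarray]
    asv_stats: pd.DataFrame
    host_stats: pd.DataFrame
    heatmap_stats: dict[str, pd.DataFrame]
    response_labels: pd.Series
    nodes: pd.DataFrame
    edge_candidates: pd.DataFrame
    net: TranskingdomNetwork
    main_component: set[str]
    topology: pd.DataFrame
    asv_ranking: pd.DataFrame
    null: topology.NullEnsembleDensity | None = None
    trace: preprocess.NormalizationTrace = field(default_factory=preprocess.NormalizationTrace)


def _treated_frames(
    qn_by_exp: dict[int, CountTable],
    host_norm: HostTable,
    meta: SampleMetadata,
    node_ids: list[str],
) -> dict[int, pd.DataFrame]:
    """Per-experiment (nodes x treated samples) data for edge construction."""
    frames = {}
    for e in sorted(qn_by_exp):
        cols = [s for s in meta.samples(experiment=e, group=Group.WD_Ch) if s in qn_by_exp[e].data.columns]
        missing = [s for s in cols if s not in host_norm.data.columns]
        if missing:
            raise ValueError(f"treated samples missing from host table: {missing[:5]}")
        combined = pd.concat([qn_by_exp[e].data[cols], host_norm.data[cols]], axis=0)
        frames[e] = combined.loc[[n for n in node_ids if n in combined.index]]
    return frames


def run_pipeline(
    study: simulate.StudyData,
    cfg: AnalysisConfig | None = None,
    run_diversity: bool = True,
    run_null: bool = True,
    null_count: int | None = None,
) -> PipelineResult:
    """Run every analysis stage on an in-memory study."""
    cfg = cfg or AnalysisConfig()
    seeds = stage_seeds(cfg.rng_seed)
    meta = study.metadata
    trace = preprocess.NormalizationTrace()

    log.info("preprocess: thresholds cumulative=%s", cfg.cumulative_abundance_threshold)
    qn_by_exp, common = preprocess.normalize_asv_pair(
        study.counts, threshold=cfg.cumulative_abundance_threshold, trace=trace
    )
    host_norm = preprocess.median_normalize_host(study.host, meta)

    alpha: dict[int, pd.DataFrame] = {}
    anosim_res: dict[int, tuple[float, float]] = {}
    pcoa_var: dict[int, np.ndarray] = {}
    if run_diversity:
        for e in sorted(qn_by_exp):
            t = qn_by_exp[e]
            alpha[e] = diversity.alpha_diversity_table(t, base=cfg.shannon_base)
            d = diversity.distance_matrix(t)
            labels = [meta.frame.at[s, "group"] for s in t.sample_ids]
            anosim_res[e] = diversity.anosim(
                d, labels, n_perm=cfg.anosim_permutations, seed=seeds["diversity"] + e
            )
            _, frac = diversity.pcoa(d)
            pcoa_var[e] = frac

    # pooled quantile-normalized ASV data (per-experiment normalization, then pooled)
    asv_pooled = pd.concat([qn_by_exp[e].data for e in sorted(qn_by_exp)], axis=1)
    asv_table = CountTable(asv_pooled, scale=qn_by_exp[min(qn_by_exp)].scale)
    asv_stats = differential.test_with_consistency(
        asv_table, meta, ("WD_Ch", "WD"), tail="two", fdr_level=cfg.asv_fdr
    )
    host_stats = differential.test_with_consistency(
        host_norm, meta, ("WD_Ch", "WD"), tail="auto", fdr_level=cfg.host_fdr
    )

    # heatmap path: per-sample relative, mean normalized across all samples
    raw_pooled = pd.concat(
        [study.counts[e].data.loc[common] for e in sorted(study.counts)], axis=1
    )
    mean_norm = preprocess.relativize_and_mean_normalize(
        CountTable(raw_pooled), trace=trace
    )
    heatmap_stats = {
        name: differential.comparison_stats(mean_norm.data, meta, comp, tail="two")
        for name, comp in differential.COMPARISONS.items()
    }
    response_labels = differential.classify_response_groups(
        heatmap_stats["WDvsND"],
        heatmap_stats["ChvsWD"],
        heatmap_stats["ChvsND"],
        p_threshold=cfg.heatmap_p_threshold,
    )

    # node selection and edge construction within the treated group
    sig_asvs = list(asv_stats.index[asv_stats["significant"]])
    sig_host = list(host_stats.index[host_stats["significant"]])
    node_rows = []
    for a in sig_asvs:
        node_rows.append(
            {
                "node_id": a,
                "kind": "ASV",
                "fc_sign": int(asv_stats.at[a, "direction"]),
                "mean_abundance": float(np.log(asv_pooled.loc[a].mean() + 1.0)),
            }
        )
    for h in sig_host:
        node_rows.append(
            {
                "node_id": h,
                "kind": study.host.kind(h),
                "fc_sign": int(host_stats.at[h, "direction"]),
                "mean_abundance": np.nan,
            }
        )
    nodes = pd.DataFrame(node_rows, columns=["node_id", "kind", "fc_sign", "mean_abundance"]).set_index(
        "node_id"
    )

    if len(nodes):
        frames = _treated_frames(qn_by_exp, host_norm, meta, list(nodes.index))
        edges = network.build_edges(frames, nodes["fc_sign"], cfg.edge_p_threshold)
    else:
        edges = pd.DataFrame(
            columns=[
                "node_a", "node_b", "rho_exp1", "rho_exp2", "rho_pooled", "p_pooled",
                "sign_consistent", "p_threshold", "causality", "kept",
            ]
        )
    net, main_comp = network.assemble_network(nodes, edges)

    g = net.to_networkx()
    asv_nodes = net.nodes_of_kind("ASV")
    host_nodes = net.nodes_of_kind("gene", "phenotype")
    if asv_nodes and host_nodes:
        topo = topology.node_topology(g, asv_nodes, host_nodes, normalized=cfg.bibc_normalized)
    else:
        topo = pd.DataFrame(
            {"degree": pd.Series(dict(g.degree), dtype=int), "bibc": 0.0}
        ).rename_axis("node_id")
    ranking = topology.rank_key_nodes(topo, restrict_to=asv_nodes) if len(topo) else topo

    null_density = None
    if run_null and net.n_edges > 0 and asv_nodes and host_nodes:
        count = null_count if null_count is not None else cfg.n_null_networks
        null_density = topology.null_ensemble(
            n=net.n_nodes,
            m=net.n_edges,
            group_sizes=(len(asv_nodes), len(host_nodes)),
            count=count,
            seed=seeds["null"],
            bins=cfg.null_grid_bins,
        )

    return PipelineResult(
        config=cfg,
        study=study,
        common_features=common,
        qn_by_exp=qn_by_exp,
        host_norm=host_norm,
        alpha=alpha,
        anosim=anosim_res,
        pcoa_variance=pcoa_var,
        asv_stats=asv_stats,
        host_stats=host_stats,
        heatmap_stats=heatmap_stats,
        response_labels=response_labels,
        nodes=nodes,
        edge_candidates=edges,
        net=net,
        main_component=main_comp,
        topology=topo,
        asv_ranking=ranking,
        null=null_density,
        trace=trace,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_run_config(path: str | Path) -> tuple[AnalysisConfig, simulate.SimulationConfig | None, dict[str, str]]:
    """Parse a YAML run configuration with optional ``analysis``,
    ``simulation`` and ``inputs`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    cfg = AnalysisConfig.from_dict(raw.get("analysis", {}))
    sim = None
    if "simulation" in raw:
        try:
            sim = simulate.SimulationConfig(**raw["simulation"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: invalid simulation section: {exc}") from exc
    inputs = raw.get("inputs", {})
    return cfg, sim, inputs


def _load_study(inputs: dict[str, str]) -> simulate.StudyData:
    required = {"counts_exp1", "counts_exp2", "host", "metadata"}
    missing = required - set(inputs)
    if missing:
        raise ConfigError(f"inputs section missing {sorted(missing)}")
    meta = SampleMetadata.read_tsv(inputs["metadata"])
    counts = {
        1: CountTable.read_tsv(inputs["counts_exp1"]),
        2: CountTable.read_tsv(inputs["counts_exp2"]),
    }
    host = HostTable.read_tsv(inputs["host"])
    truth = simulate.GroundTruth(
        membership=pd.Series(dtype=object),
        bridge_asv_id="",
        bridge_gene_id="",
        bridge_phenotype_id="",
        group_log_means=pd.DataFrame(),
    )
    return simulate.StudyData(counts=counts, host=host, metadata=meta, truth=truth)


def run_all(config_path: str | Path, outdir: str | Path, seed: int | None = None) -> dict[str, Any]:
    """Run the whole pipeline from a config file and write all stage outputs
    plus a run manifest to ``outdir``. Returns the manifest."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg, sim_cfg, inputs = load_run_config(config_path)
    if seed is not None:
        cfg = dataclasses.replace(cfg, rng_seed=seed)
        if sim_cfg is not None:
            sim_cfg = dataclasses.replace(sim_cfg, seed=stage_seeds(seed)["simulate"])

    stage = "simulate"
    try:
        if sim_cfg is not None:
            study = simulate.generate_study(sim_cfg)
            for e, t in study.counts.items():
                t.write_tsv(outdir / f"counts_exp{e}.tsv")
            study.host.write_tsv(outdir / "host.tsv")
            study.metadata.write_tsv(outdir / "metadata.tsv")
            study.truth.to_json(outdir / "ground_truth.json")
        else:
            study = _load_study(inputs)

        stage = "pipeline"
        result = run_pipeline(study, cfg)

        stage = "write"
        for e, t in result.qn_by_exp.items():
            t.write_tsv(outdir / f"asv_quantile_normalized_exp{e}.tsv")
        result.host_norm.write_tsv(outdir / "host_median_normalized.tsv")
        for e, a in result.alpha.items():
            a.to_csv(outdir / f"alpha_diversity_exp{e}.tsv", sep="\t")
        result.asv_stats.to_csv(outdir / "differential_asv.tsv", sep="\t")
        result.host_stats.to_csv(outdir / "differential_host.tsv", sep="\t")
        result.response_labels.to_frame().to_csv(outdir / "response_groups.tsv", sep="\t")
        result.edge_candidates.to_csv(outdir / "edge_candidates.tsv", sep="\t", index=False)
        write_network(result.net, outdir / "network", topology=result.topology)
        result.asv_ranking.to_csv(outdir / "asv_ranking.tsv", sep="\t")
        if result.null is not None:
            result.null.to_frame().to_csv(outdir / "null_ensemble.tsv", sep="\t", index=False)
        diversity_json = {
            str(e): {"anosim_R": r, "anosim_p": p, "pcoa_pc1": float(result.pcoa_variance[e][0])}
            for e, (r, p) in result.anosim.items()
        }
        (outdir / "diversity.json").write_text(json.dumps(diversity_json, indent=1))
        (outdir / "normalization_trace.json").write_text(json.dumps(result.trace.to_list(), indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "config": cfg.to_dict(),
        "simulation": dataclasses.asdict(sim_cfg) if sim_cfg is not None else None,
        "seed": cfg.rng_seed,
        "stage_seeds": stage_seeds(cfg.rng_seed),
        "stages": list(STAGES),
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.is_file() and p.name != "manifest.json"
        },
        "n_nodes": result.net.n_nodes,
        "n_edges": result.net.n_edges,
        "elapsed_seconds": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
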