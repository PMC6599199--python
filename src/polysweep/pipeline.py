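"""End-to-end orchestration: simulate -> filter -> diversity -> scan ->
regions -> expression, from one YAML config, with a checksummed manifest.

Every stage writes plain-text TSV/BED outputs and can be re-run from the
files of the previous stage. Given the same config and seed, deterministic
stages reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import regions as reg
from . import sim
from . import variants as var
from . import xpclr
from .expression import (
    ExpressionMatrix,
    call_degs,
    local_clustering,
    node_fold_change,
    subgenome_deg_test,
    unique_degs,
)
from .genmap import GeneticMap

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

#: module parameter defaults, shared by the config loader and the CLI
DEFAULTS = {
    "filter": dict(min_depth=10, min_mq=30, min_call_rate=0.5, min_maf=0.05,
                   preset="group1"),
    "diversity": dict(window=100_000, step=25_000),
    "scan": dict(window_morgans=0.005, max_snps=100, grid_bp=2000,
                 r2_cutoff=0.7),
    "regions": dict(window=20_000, step=10_000, window_q=0.20, region_q=0.05,
                    ratio_q=0.50),
    "expression": dict(lfc=1.0, alpha=0.05),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see DEFAULTS for parameter values)."""

    out_dir: str
    seed: int = 0
    simulate: dict = None  # SimConfig fields (+ optional sweep / expression)
    inputs: dict = field(default_factory=dict)  # explicit file paths
    filter: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "out_dir" not in raw:
            raise ValueError("config must set out_dir")
        return cls(**raw)

    def stage_params(self, stage: str) -> dict:
        params = dict(DEFAULTS.get(stage, {}))
        params.update(getattr(self, stage) or {})
        return params


def load_network(nodes_path, edges_path) -> nx.Graph:
    """Rebuild the reaction graph from the node/edge TSVs the simulator writes."""
    nodes = pd.read_csv(nodes_path, sep="\t")
    edges = pd.read_csv(edges_path, sep="\t")
    graph = nx.Graph()
    for _, row in nodes.iterrows():
        members = (
            str(row["orthologs"]).split(";")
            if isinstance(row["orthologs"], str) and row["orthologs"]
            else []
        )
        graph.add_node(row["node"], orthologs=members)
    graph.add_edges_from(edges.itertuples(index=False, name=None))
    return graph


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; return (and write) the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "outputs": []}

    def record(path, stage, params):
        manifest["outputs"].append(
            {
                "path": str(path),
                "stage": stage,
                "params": {k: repr(v) for k, v in params.items()},
                "sha256": _sha256(path),
            }
        )

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(8) % (2**31)

    # ---- stage: simulate ---------------------------------------------------
    inputs = dict(config.inputs)
    truth = {}
    if config.simulate is not None:
        simspec = dict(config.simulate)
        sweep_spec = simspec.pop("sweep", None)
        expr_spec = simspec.pop("expression", None)
        cfg = sim.SimConfig(seed=int(seeds[0]), **simspec)
        sweep = sim.SweepSpec(**sweep_spec) if sweep_spec else None
        expr_cfg = (
            sim.ExprSimConfig(seed=int(seeds[1]), **expr_spec) if expr_spec else None
        )
        try:
            bundle = sim.simulate_to_dir(out / "inputs", cfg, sweep, expr_cfg)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage simulate failed: {exc}") from exc
        inputs.update(bundle["paths"])
        truth = bundle["truth"]
        for key, path in bundle["paths"].items():
            record(path, "simulate", {"input": key})

    # ---- stage: filter -----------------------------------------------------
    fparams = config.stage_params("filter")
    preset = fparams.pop("preset", None)
    if preset:
        fparams.update(var.FILTER_PRESETS[preset])
    try:
        table = var.read_vcf(inputs["vcf"])
        report = {}
        table = var.filter_variants(table, report=report, **fparams)
        pd.Series(report, name="removed").rename_axis("rule").to_csv(
            out / "filter_report.tsv", sep="\t"
        )
        var.write_vcf(table, out / "filtered.vcf")
    except KeyError as exc:
        raise StageError(f"stage filter failed: missing input {exc}") from exc
    record(out / "filtered.vcf", "filter", fparams)
    record(out / "filter_report.tsv", "filter", fparams)
    log.info("filter: %d sites retained (%s removed)", len(table), report)

    groups_df = pd.read_csv(inputs["groups"], sep="\t")
    groups = {
        g: list(sub["sample"]) for g, sub in groups_df.groupby("group")
    }
    if set(groups) != {"ref", "obj"}:
        raise StageError("sample groups file must define exactly 'ref' and 'obj'")
    counts = var.allele_counts(table, groups)
    gmap = GeneticMap.read_tsv(inputs["map"])
    positions = table.sites["pos"].to_numpy()
    chrom = str(table.sites["chrom"].iloc[0]) if len(table) else "chr"
    chrom_length = int(gmap.pos_bp[-1])

    # ---- stage: diversity --------------------------------------------------
    dparams = config.stage_params("diversity")
    rparams = config.stage_params("regions")
    tracks = {}
    for name in ("ref", "obj"):
        tracks[f"pi_{name}"] = div.windowed_pi(
            counts[name], positions, chrom_length, chrom,
            window=dparams["window"], step=dparams["step"],
        )
    tracks["fst"] = div.windowed_fst(
        counts["ref"], counts["obj"], positions, chrom_length, chrom,
        window=dparams["window"], step=dparams["step"],
    )
    # fine-grained pi on the sweep-region grid, for the ratio track
    pi_ref_fine = div.windowed_pi(
        counts["ref"], positions, chrom_length, chrom,
        window=rparams["window"], step=rparams["step"],
    )
    pi_obj_fine = div.windowed_pi(
        counts["obj"], positions, chrom_length, chrom,
        window=rparams["window"], step=rparams["step"],
    )
    tracks["pi_ratio"] = div.pi_ratio_track(pi_ref_fine, pi_obj_fine)
    for name, track in tracks.items():
        path = out / f"{name}.tsv"
        track.write_tsv(path)
        record(path, "diversity", dparams)

    # ---- stage: scan -------------------------------------------------------
    sparams = config.stage_params("scan")
    model = xpclr.estimate_omega(counts["ref"], counts["obj"])
    params = xpclr.ScanParams(seed=int(seeds[2]), **sparams)
    obj_idx = table.sample_indices(groups["obj"])
    hap_obj = table.haplotypes(obj_idx)
    score = xpclr.xpclr_scan(
        counts["ref"], counts["obj"], hap_obj, positions, gmap, params, model,
        chrom=chrom,
    )
    score.to_csv(out / "xpclr_scores.tsv", sep="\t", index=False)
    record(out / "xpclr_scores.tsv", "scan", {**sparams, "omega": model.omega})
    log.info("scan: omega_hat=%.4f, %d grid points", model.omega, len(score))

    # ---- stage: regions ----------------------------------------------------
    mean_track = reg.mean_score_track(
        score, chrom_length, window=rparams["window"], step=rparams["step"]
    )
    mean_track.write_tsv(out / "xpclr_mean_track.tsv")
    score_regions = reg.call_score_regions(
        mean_track, window_q=rparams["window_q"], region_q=rparams["region_q"]
    )
    ratio_regions = reg.call_ratio_regions(
        tracks["pi_ratio"], ratio_q=rparams["ratio_q"]
    )
    final_regions, overlap = reg.intersect_regions(score_regions, ratio_regions)
    for name, rs in (
        ("regions_xpclr", score_regions),
        ("regions_pi_ratio", ratio_regions),
        ("regions_final", final_regions),
    ):
        rs.write_tsv(out / f"{name}.tsv")
        record(out / f"{name}.tsv", "regions", rparams)
    manifest["overlap_fraction"] = overlap
    log.info(
        "regions: %d score, %d ratio, %d final (overlap %.3f)",
        len(score_regions), len(ratio_regions), len(final_regions), overlap,
    )

    # ---- stage: expression -------------------------------------------------
    if "fpkm" in inputs:
        eparams = config.stage_params("expression")
        fpkm = pd.read_csv(inputs["fpkm"], sep="\t", index_col=0)
        clusters = pd.read_csv(inputs["clusters"], sep="\t", index_col=0)["cluster"]
        subgenome = None
        if "annotation" in inputs:
            ann = pd.read_csv(inputs["annotation"], sep="\t", index_col=0)
            subgenome = ann["subgenome"].reindex(fpkm.index)
        expr = ExpressionMatrix(fpkm=fpkm, clusters=clusters, subgenome=subgenome)
        ref_cluster = eparams.pop("ref_cluster", None) or clusters.iloc[0]
        deg_tables = {}
        for cl in [c for c in clusters.unique() if c != ref_cluster]:
            deg = call_degs(expr, ref_cluster, cl, **eparams)
            deg.to_csv(out / f"degs_{cl}.tsv", sep="\t")
            record(out / f"degs_{cl}.tsv", "expression", eparams)
            deg_tables[cl] = deg
        uniq, partition = unique_degs(deg_tables)
        pd.Series(uniq, name="unique_degs").rename_axis("cluster").to_csv(
            out / "unique_degs.tsv", sep="\t"
        )
        record(out / "unique_degs.tsv", "expression", eparams)
        manifest["venn_partition"] = {
            "+".join(sorted(k)): v for k, v in partition.items()
        }
        if subgenome is not None:
            sub_stats = {
                cl: subgenome_deg_test(deg, subgenome)
                for cl, deg in deg_tables.items()
            }
            pd.DataFrame(sub_stats).T.to_csv(out / "subgenome_deg_test.tsv", sep="\t")
            record(out / "subgenome_deg_test.tsv", "expression", eparams)
        if "network_nodes" in inputs and "orthologs" in inputs:
            expr.ortholog = pd.read_csv(
                inputs["orthologs"], sep="\t", index_col=0
            )["ortholog"].reindex(fpkm.index)
            graph = load_network(inputs["network_nodes"], inputs["network_edges"])
            coeffs = pd.Series(local_clustering(graph), name="clustering")
            for cl, deg in deg_tables.items():
                stats = node_fold_change(expr, graph, deg, ref_cluster, cl)
                stats = stats.join(coeffs)
                stats.to_csv(out / f"network_{cl}.tsv", sep="\t")
                record(out / f"network_{cl}.tsv", "network", eparams)
                for node in graph.nodes:
                    graph.nodes[node][f"fold_change_{cl}"] = float(
                        stats.loc[node, "fold_change"]
                    )
                    graph.nodes[node][f"color_{cl}"] = str(stats.loc[node, "color"])
                    graph.nodes[node]["clustering"] = float(coeffs[node])
            gml = out / "network_annotated.graphml"
            export = graph.copy()
            for node in export.nodes:  # GraphML cannot hold list attributes
                export.nodes[node]["orthologs"] = ";".join(
                    export.nodes[node].get("orthologs", [])
                )
            nx.write_graphml(export, gml)
            record(gml, "network", eparams)

    manifest["truth"] = truth
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
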