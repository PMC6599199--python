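"""Synthetic two-population genotype, expression, and annotation generators.

The neutral model is the same truncated-Gaussian drift model the sweep scan
assumes: an ancestral allele frequency p is drawn from a neutral-like
spectrum, the reference population keeps p1 = p, and the object population
frequency is Normal(p1, omega * p1 * (1 - p1)) with mass outside [0, 1]
collapsed onto the boundaries (drift to loss/fixation). Haplotypes are then
binomial samples of the population frequencies, so every downstream estimator
can be checked against known truth.

A hitchhiking sweep is implanted by the capture-probability transform: a
neutral frequency y at genetic distance d from the selected site becomes
x = kappa + (1 - kappa) * y with probability y (the lineage was captured by
the sweeping haplotype) and x = (1 - kappa) * y otherwise, with
kappa = exp(-d / sigma).

Expression matrices are log-normal FPKM with a planted set of differentially
expressed genes per non-reference cluster; annotation and metabolic-network
tables are toy-structured but carry every field the overlay statistics need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .genmap import GeneticMap, linear_map

__all__ = [
    "SimConfig",
    "SweepSpec",
    "ExprSimConfig",
    "simulate_neutral_pair",
    "implant_sweep",
    "simulate_expression",
    "make_annotation_and_network",
    "write_vcf_arrays",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Two-population neutral simulation settings.

    n_ref / n_obj are chromosome (haplotype) counts, even and >= 4 so that
    diploid genotypes can be formed by pairing consecutive haplotypes.
    omega is the genome-wide drift variance scale; ancestral_sfs is
    ("loguniform", lo, hi) giving density proportional to 1/x on [lo, hi].
    """

    n_ref: int = 60
    n_obj: int = 60
    chrom_length: int = 2_000_000
    n_snps: int = 10_000
    omega: float = 0.1
    ancestral_sfs: tuple = ("loguniform", 0.02, 0.98)
    map_rate: float = 1.0  # cM per Mb
    seed: int = 0
    chrom: str = "A01"
    missing_rate: float = 0.0
    ld_rho_per_kb: float = 0.0  # >0 switches on the Markov copy-with-decay mode

    def validate(self) -> None:
        for name in ("n_ref", "n_obj"):
            v = getattr(self, name)
            if v < 4 or v % 2:
                raise ConfigError(f"{name} must be even and >= 4, got {v}")
        if self.omega < 0:
            raise ConfigError(f"omega must be >= 0, got {self.omega}")
        if self.n_snps < 1:
            raise ConfigError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.chrom_length < self.n_snps:
            raise ConfigError("chrom_length too small for n_snps distinct positions")
        kind, lo, hi = self.ancestral_sfs
        if kind != "loguniform" or not (0 < lo < hi < 1):
            raise ConfigError(f"ancestral_sfs invalid: {self.ancestral_sfs}")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        if self.ld_rho_per_kb < 0 or self.ld_rho_per_kb >= 1:
            raise ConfigError(f"ld_rho_per_kb must be in [0,1), got {self.ld_rho_per_kb}")


@dataclass
class SweepSpec:
    """A localized hitchhiking event in one population."""

    position: int
    sigma: float  # sweep scale, Morgans
    direction: str = "obj"  # population carrying the sweep

    def validate(self, chrom_length: int) -> None:
        if self.sigma <= 0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")
        if not (0 <= self.position < chrom_length):
            raise ConfigError(
                f"position {self.position} outside chromosome [0, {chrom_length})"
            )
        if self.direction not in ("ref", "obj"):
            raise ConfigError(f"direction must be 'ref' or 'obj', got {self.direction}")


@dataclass
class NeutralPair:
    """Output bundle of :func:`simulate_neutral_pair`."""

    hap_ref: np.ndarray  # (n_snps, n_ref) int8 in {0,1}
    hap_obj: np.ndarray  # (n_snps, n_obj)
    positions: np.ndarray  # strictly increasing bp, int64
    genetic_map: GeneticMap
    p_ref: np.ndarray  # true population frequencies
    p_obj: np.ndarray
    config: SimConfig


def _ancestral_freqs(rng: np.random.Generator, n: int, sfs: tuple) -> np.ndarray:
    _, lo, hi = sfs
    u = rng.random(n)
    return lo * (hi / lo) ** u  # inverse CDF of density ~ 1/x on [lo, hi]


def _sample_haplotypes(
    rng: np.random.Generator,
    p: np.ndarray,
    n_hap: int,
    positions: np.ndarray,
    rho_per_kb: float,
) -> np.ndarray:
    """Bernoulli(p) per chromosome; optional Gaussian-copula AR(1) LD.

    In the LD mode, a latent standard-normal AR(1) with inter-site correlation
    rho_per_kb ** (delta_bp / 1000) is thresholded at the per-site quantile, so
    marginals stay Bernoulli(p) while adjacent sites are positively correlated
    with distance decay.
    """
    n_snps = len(p)
    if rho_per_kb <= 0:
        return (rng.random((n_snps, n_hap)) < p[:, None]).astype(np.int8)
    from scipy.stats import norm

    r = rho_per_kb ** (np.diff(positions) / 1000.0)
    z = np.empty((n_snps, n_hap))
    z[0] = rng.standard_normal(n_hap)
    eps = rng.standard_normal((n_snps - 1, n_hap))
    for i in range(1, n_snps):
        z[i] = r[i - 1] * z[i - 1] + math.sqrt(1.0 - r[i - 1] ** 2) * eps[i - 1]
    thresh = norm.ppf(p)[:, None]
    return (z < thresh).astype(np.int8)


def simulate_neutral_pair(cfg: SimConfig) -> NeutralPair:
    """Simulate phased haplotypes for two populations under neutral drift."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    positions = np.sort(
        rng.choice(cfg.chrom_length, size=cfg.n_snps, replace=False)
    ).astype(np.int64)
    p1 = _ancestral_freqs(rng, cfg.n_snps, cfg.ancestral_sfs)
    if cfg.omega > 0:
        sd = np.sqrt(cfg.omega * p1 * (1.0 - p1))
        p2 = np.clip(rng.normal(p1, sd), 0.0, 1.0)
    else:
        p2 = p1.copy()
    hap_ref = _sample_haplotypes(rng, p1, cfg.n_ref, positions, cfg.ld_rho_per_kb)
    hap_obj = _sample_haplotypes(rng, p2, cfg.n_obj, positions, cfg.ld_rho_per_kb)
    gmap = linear_map(cfg.chrom_length, cfg.map_rate)
    return NeutralPair(hap_ref, hap_obj, positions, gmap, p1, p2, cfg)


def implant_sweep(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    genetic_map: GeneticMap,
    spec: SweepSpec,
    seed: int,
) -> np.ndarray:
    """Apply the capture-probability transform around a selected site.

    Per site at genetic distance d (Morgans) from spec.position, with
    kappa = exp(-d / sigma): the empirical frequency y becomes
    x = kappa + (1 - kappa) * y with probability y, else x = (1 - kappa) * y,
    and the column is resampled Bernoulli(x). Columns whose frequency is
    unchanged (kappa == 0) are left untouched so the no-sweep limit is exact.
    """
    chrom_length = int(genetic_map.pos_bp[-1])
    spec.validate(chrom_length)
    rng = np.random.default_rng(seed)
    n_snps, n_hap = haplotypes.shape
    d = np.abs(genetic_map.morgans(positions) - genetic_map.morgans(spec.position))
    kappa = np.exp(-d / spec.sigma)
    y = haplotypes.mean(axis=1)
    captured = rng.random(n_snps) < y
    x = np.where(captured, kappa + (1.0 - kappa) * y, (1.0 - kappa) * y)
    out = haplotypes.copy()
    # a perturbation below half an allele count is unobservable in a sample
    # of n_hap chromosomes; leaving those columns untouched keeps the sweep
    # footprint exactly local (and makes the sigma -> 0 limit exact)
    changed = (x != y) & (kappa > 0.5 / n_hap)
    if np.any(changed):
        out[changed] = (
            rng.random((int(changed.sum()), n_hap)) < x[changed, None]
        ).astype(np.int8)
    return out


@dataclass
class ExprSimConfig:
    """Log-normal FPKM simulation with planted differential expression."""

    clusters: list = field(
        default_factory=lambda: [("WEAm", 20), ("S", 20), ("R", 20)]
    )
    n_genes: int = 2_000
    de_fraction: float = 0.10
    effect_log2: float = 2.0
    noise_sd: float = 0.5
    subgenome_split: float = 0.55
    baseline_mean: float = 4.0  # mean log2 FPKM
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not self.clusters or any(n < 1 for _, n in self.clusters):
            raise ConfigError("clusters must be non-empty with >= 1 accession each")
        if not (0 <= self.de_fraction <= 1):
            raise ConfigError(f"de_fraction must be in [0,1], got {self.de_fraction}")
        if self.effect_log2 < 0:
            raise ConfigError(f"effect_log2 must be >= 0, got {self.effect_log2}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not (0 <= self.subgenome_split <= 1):
            raise ConfigError(
                f"subgenome_split must be in [0,1], got {self.subgenome_split}"
            )
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")


def simulate_expression(cfg: ExprSimConfig):
    """Return (ExpressionMatrix, truth) with truth[gene, cluster] = True iff DE.

    The first cluster in cfg.clusters is the reference; each other cluster
    gets an independent random de_fraction of genes shifted by
    +/- effect_log2 on the log2 scale, sign random per (gene, cluster).
    """
    from .expression import ExpressionMatrix

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    accessions, labels = [], []
    for name, n_acc in cfg.clusters:
        for j in range(n_acc):
            accessions.append(f"{name}_{j:02d}")
            labels.append(name)

    ref_name = cfg.clusters[0][0]
    truth = pd.DataFrame(
        False, index=genes, columns=[n for n, _ in cfg.clusters[1:]]
    )
    log2fpkm = np.empty((cfg.n_genes, len(accessions)))
    col = 0
    for name, n_acc in cfg.clusters:
        center = np.repeat(mu[:, None], n_acc, axis=1)
        if name != ref_name and cfg.de_fraction > 0:
            n_de = int(round(cfg.de_fraction * cfg.n_genes))
            de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
            sign = rng.choice([-1.0, 1.0], size=n_de)
            center[de_idx] += (sign * cfg.effect_log2)[:, None]
            truth.iloc[de_idx, truth.columns.get_loc(name)] = True
        log2fpkm[:, col : col + n_acc] = center + rng.normal(
            0.0, cfg.noise_sd, size=(cfg.n_genes, n_acc)
        )
        col += n_acc

    fpkm = pd.DataFrame(2.0 ** log2fpkm, index=genes, columns=accessions)
    n_a = int(round(cfg.subgenome_split * cfg.n_genes))
    subgenome = pd.Series(
        ["A"] * n_a + ["C"] * (cfg.n_genes - n_a), index=genes, name="subgenome"
    )
    clusters = pd.Series(labels, index=accessions, name="cluster")
    expr = ExpressionMatrix(fpkm=fpkm, clusters=clusters, subgenome=subgenome)
    return expr, truth


def make_annotation_and_network(
    n_genes: int,
    chrom_lengths: dict,
    subgenome_split: float = 0.55,
    mean_genes_per_node: float = 2.0,
    n_nodes: int = 50,
    edge_prob: float = 0.08,
    ortholog_fraction: float = 0.8,
    seed: int = 0,
):
    """Toy gene annotation, ortholog map, and reaction network.

    Returns (annotation DataFrame, ortholog Series, networkx.Graph). Node
    attribute ``orthologs`` lists the ortholog IDs a reaction owns; genes map
    many-to-one onto ortholog IDs, so one ortholog may have A and C copies.
    """
    if n_genes < 1:
        raise ConfigError(f"n_genes must be >= 1, got {n_genes}")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    a_chroms = [c for c in chroms if c.startswith("A")] or chroms
    c_chroms = [c for c in chroms if c.startswith("C")] or chroms

    n_a = int(round(subgenome_split * n_genes))
    rows = []
    per_chrom_counts = {}
    for i in range(n_genes):
        sub = "A" if i < n_a else "C"
        pool = a_chroms if sub == "A" else c_chroms
        chrom = pool[i % len(pool)]
        per_chrom_counts[chrom] = per_chrom_counts.get(chrom, 0) + 1
        rows.append((f"gene{i:05d}", chrom, sub))
    # lay genes out non-overlapping per chromosome
    ann_rows = []
    offsets = {c: 0 for c in chroms}
    for gene, chrom, sub in rows:
        length = int(rng.integers(500, 5000))
        gap = int(rng.integers(100, 2000))
        start = offsets[chrom] + gap
        end = start + length
        if end > chrom_lengths[chrom]:
            start = offsets[chrom] % max(chrom_lengths[chrom] - length, 1)
            end = start + length
        offsets[chrom] = end
        ann_rows.append((gene, chrom, start, end, sub))
    annotation = pd.DataFrame(
        ann_rows, columns=["gene", "chrom", "start", "end", "subgenome"]
    ).set_index("gene")

    n_orth = max(1, int(round(ortholog_fraction * n_genes)))
    orth_ids = [f"AT{1 + i % 5}G{10 * (i + 1):05d}" for i in range(n_orth)]
    has_orth = rng.random(n_genes) < ortholog_fraction
    assigned = rng.integers(0, n_orth, size=n_genes)
    ortholog = pd.Series(
        [orth_ids[assigned[i]] if has_orth[i] else None for i in range(n_genes)],
        index=annotation.index,
        name="ortholog",
    )

    graph = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, {i: f"RXN{i:03d}" for i in range(n_nodes)})
    for node in graph.nodes:
        k = rng.poisson(mean_genes_per_node) if mean_genes_per_node > 0 else 0
        members = (
            list(rng.choice(orth_ids, size=min(k, n_orth), replace=False))
            if k > 0
            else []
        )
        graph.nodes[node]["orthologs"] = members
    return annotation, ortholog, graph


# ---------------------------------------------------------------------------
# file writers (the simulator doubles as the fixture factory for the pipeline)
# ---------------------------------------------------------------------------

_FUNC_CLASSES = np.array(["synonymous", "noncoding", "other"])


def write_vcf_arrays(
    path,
    chrom: str,
    positions: np.ndarray,
    genotypes: np.ndarray,
    samples: list,
    depth: np.ndarray = None,
    mapq: np.ndarray = None,
    func_class: np.ndarray = None,
    phased: bool = True,
) -> None:
    """Write a minimal VCF 4.2 with INFO DP/MQ/FC and GT genotypes.

    genotypes: int8 (n_sites, n_samples, 2), -1 = missing allele.
    Positions are 0-based here and written 1-based.
    """
    n_sites = len(positions)
    if depth is None:
        depth = np.full(n_sites, 50)
    if mapq is None:
        mapq = np.full(n_sites, 60.0)
    if func_class is None:
        func_class = np.full(n_sites, "synonymous")
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Mapping depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write(
            '##INFO=<ID=FC,Number=1,Type=String,Description='
            '"Functional class (synonymous/noncoding/other)">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i in range(n_sites):
            gts = []
            for s in range(len(samples)):
                a, b = genotypes[i, s]
                fa = "." if a < 0 else str(int(a))
                fb = "." if b < 0 else str(int(b))
                gts.append(f"{fa}{sep}{fb}")
            info = f"DP={int(depth[i])};MQ={float(mapq[i]):g};FC={func_class[i]}"
            fh.write(
                f"{chrom}\t{int(positions[i]) + 1}\t.\tA\tG\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def haplotypes_to_genotypes(hap: np.ndarray) -> np.ndarray:
    """Pair consecutive haplotypes into diploid genotypes (n_sites, n/2, 2)."""
    n_sites, n_hap = hap.shape
    return hap.reshape(n_sites, n_hap // 2, 2)


def simulate_to_dir(
    out_dir,
    cfg: SimConfig,
    sweep: SweepSpec = None,
    expr_cfg: ExprSimConfig = None,
    depth_mean: float = 50.0,
    low_quality_fraction: float = 0.1,
) -> dict:
    """Generate the full input bundle for the pipeline under out_dir.

    A fraction of sites gets sub-threshold depth/MQ and a mix of functional
    classes so the filter cascade has real work to do. Returns a manifest of
    written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair = simulate_neutral_pair(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9151]))
    hap_obj = pair.hap_obj
    if sweep is not None:
        target = hap_obj if sweep.direction == "obj" else pair.hap_ref
        swept = implant_sweep(
            target, pair.positions, pair.genetic_map, sweep, int(rng.integers(2**31))
        )
        if sweep.direction == "obj":
            hap_obj = swept
        else:
            pair.hap_ref = swept

    n_sites = cfg.n_snps
    depth = rng.poisson(depth_mean, n_sites)
    mapq = np.round(rng.normal(55, 5, n_sites), 1)
    low = rng.random(n_sites) < low_quality_fraction
    depth[low] = rng.integers(1, 11, int(low.sum()))
    mapq[low & (rng.random(n_sites) < 0.5)] = 20.0
    func_class = _FUNC_CLASSES[rng.choice(3, n_sites, p=[0.45, 0.45, 0.10])]

    gt_ref = haplotypes_to_genotypes(pair.hap_ref)
    gt_obj = haplotypes_to_genotypes(hap_obj)
    genotypes = np.concatenate([gt_ref, gt_obj], axis=1)
    if cfg.missing_rate > 0:
        miss = rng.random(genotypes.shape[:2]) < cfg.missing_rate
        genotypes = genotypes.copy()
        genotypes[miss] = -1
    samples = [f"REF_{i:03d}" for i in range(cfg.n_ref // 2)] + [
        f"OBJ_{i:03d}" for i in range(cfg.n_obj // 2)
    ]

    paths = {}
    paths["vcf"] = str(out / "variants.vcf")
    write_vcf_arrays(
        paths["vcf"], cfg.chrom, pair.positions, genotypes, samples,
        depth=depth, mapq=mapq, func_class=func_class,
    )
    paths["map"] = str(out / "genetic_map.tsv")
    pair.genetic_map.write_tsv(paths["map"])
    groups = pd.DataFrame(
        {"sample": samples, "group": ["ref"] * (cfg.n_ref // 2) + ["obj"] * (cfg.n_obj // 2)}
    )
    paths["groups"] = str(out / "sample_groups.tsv")
    groups.to_csv(paths["groups"], sep="\t", index=False)
    truth = {
        "sweep_position": None if sweep is None else int(sweep.position),
        "omega": cfg.omega,
    }

    if expr_cfg is not None:
        expr, de_truth = simulate_expression(expr_cfg)
        paths["fpkm"] = str(out / "fpkm.tsv")
        expr.fpkm.to_csv(paths["fpkm"], sep="\t")
        paths["clusters"] = str(out / "cluster_labels.tsv")
        expr.clusters.rename("cluster").to_csv(paths["clusters"], sep="\t")
        ann, orth, graph = make_annotation_and_network(
            expr_cfg.n_genes,
            {cfg.chrom: cfg.chrom_length, "C01": cfg.chrom_length},
            subgenome_split=expr_cfg.subgenome_split,
            seed=expr_cfg.seed + 1,
        )
        paths["annotation"] = str(out / "gene_annotation.tsv")
        ann.to_csv(paths["annotation"], sep="\t")
        paths["orthologs"] = str(out / "ortholog_map.tsv")
        orth.to_csv(paths["orthologs"], sep="\t")
        paths["network_edges"] = str(out / "network_edges.tsv")
        pd.DataFrame(graph.edges, columns=["node_a", "node_b"]).to_csv(
            paths["network_edges"], sep="\t", index=False
        )
        paths["network_nodes"] = str(out / "network_nodes.tsv")
        pd.DataFrame(
            [(n, ";".join(graph.nodes[n]["orthologs"])) for n in graph.nodes],
            columns=["node", "orthologs"],
        ).to_csv(paths["network_nodes"], sep="\t", index=False)
        paths["de_truth"] = str(out / "de_truth.tsv")
        de_truth.to_csv(paths["de_truth"], sep="\t")
    return {"paths": paths, "truth": truth}
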