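"""Differential expression and metabolic-network overlay statistics.

DEGs are called between a reference cluster and each other cluster from an
FPKM matrix: log2 ratio of group-mean FPKM (pseudocount delta) with a Welch
two-sample test on log2(FPKM + delta), calling a gene up/down iff
|log2 ratio| > 1.0 (strict) and p < 0.05 (strict, uncorrected by default; a
Benjamini-Hochberg option exists). Downstream: per-cluster unique-DEG Venn
partition, an A/C sub-genome asymmetry chi-square test, and a reaction-node
overlay that pools FPKM sums of DEG-mapped orthologs per node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "call_degs",
    "unique_degs",
    "subgenome_deg_test",
    "node_fold_change",
    "local_clustering",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """FPKM genes x accessions with cluster labels and gene metadata."""

    fpkm: pd.DataFrame  # genes x accessions, nonnegative
    clusters: pd.Series  # accession -> cluster label
    subgenome: pd.Series = None  # gene -> 'A' / 'C'
    ortholog: pd.Series = None  # gene -> ortholog ID (or None)

    def __post_init__(self):
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM must be nonnegative")
        missing = set(self.fpkm.columns) - set(self.clusters.index)
        if missing:
            raise ValueError(f"accessions without cluster label: {sorted(missing)}")

    def accessions_of(self, cluster: str) -> list:
        acc = [a for a in self.fpkm.columns if self.clusters[a] == cluster]
        if not acc:
            raise KeyError(f"cluster {cluster!r} has no accessions")
        return acc


def call_degs(
    expr: ExpressionMatrix,
    ref_cluster: str,
    other_cluster: str,
    lfc: float = 1.0,
    alpha: float = 0.05,
    delta: float = 1.0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Call DEGs of other_cluster relative to ref_cluster.

    Returns a DataFrame indexed by gene with columns log2_ratio, p_value,
    call in {'up', 'down', 'ns'}. log2_ratio = log2((mean_other + delta) /
    (mean_ref + delta)); the test is Welch's t on log2(FPKM + delta).
    Both thresholds are strict, so |log2_ratio| exactly equal to lfc is ns.
    """
    ref = expr.fpkm[expr.accessions_of(ref_cluster)]
    oth = expr.fpkm[expr.accessions_of(other_cluster)]
    if ref.shape[1] < 2 or oth.shape[1] < 2:
        raise ValueError("need >= 2 accessions per cluster for the Welch test")
    log2_ratio = np.log2((oth.mean(axis=1) + delta) / (ref.mean(axis=1) + delta))
    lref = np.log2(ref.to_numpy() + delta)
    loth = np.log2(oth.to_numpy() + delta)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(loth, lref, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both ties
    if bh_correct:
        p = _bh(p)
    call = np.where(
        (np.abs(log2_ratio) > lfc) & (p < alpha),
        np.where(log2_ratio > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {"log2_ratio": log2_ratio, "p_value": p, "call": call},
        index=expr.fpkm.index,
    )


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def unique_degs(deg_tables: dict):
    """Venn partition of DEG sets across comparisons.

    deg_tables: {cluster_name: DEG DataFrame} sharing one gene universe.
    Returns (unique_counts, partition): unique_counts maps each cluster to
    the number of genes called in exactly that comparison; partition maps a
    frozenset of cluster names to its count (only non-empty memberships).
    """
    names = list(deg_tables)
    universe = None
    sets = {}
    for name, tab in deg_tables.items():
        idx = frozenset(tab.index)
        if universe is None:
            universe = idx
        elif idx != universe:
            raise ValueError("DEG tables do not share a gene universe")
        sets[name] = set(tab.index[tab["call"] != "ns"])
    partition = {}
    union = set().union(*sets.values()) if sets else set()
    for gene in union:
        member = frozenset(n for n in names if gene in sets[n])
        partition[member] = partition.get(member, 0) + 1
    unique_counts = {
        n: partition.get(frozenset([n]), 0) for n in names
    }
    return unique_counts, partition


def subgenome_deg_test(deg_table: pd.DataFrame, subgenome: pd.Series):
    """A/C sub-genome DEG asymmetry: observed DEG split vs the tested-gene
    split, Pearson chi-square with 1 df (no continuity correction).

    Returns dict with deg_a, deg_c, ratio, expected_a, expected_c, chi2, p.
    """
    sub = subgenome.reindex(deg_table.index)
    tested_a = int((sub == "A").sum())
    tested_c = int((sub == "C").sum())
    if tested_a == 0 or tested_c == 0:
        raise ValueError("both sub-genomes need >= 1 tested gene")
    is_deg = deg_table["call"] != "ns"
    deg_a = int((is_deg & (sub == "A")).sum())
    deg_c = int((is_deg & (sub == "C")).sum())
    total = deg_a + deg_c
    exp_a = total * tested_a / (tested_a + tested_c)
    exp_c = total * tested_c / (tested_a + tested_c)
    if exp_a == 0 or exp_c == 0:
        raise ValueError("expected count of zero; no DEGs to test")
    chi2 = (deg_a - exp_a) ** 2 / exp_a + (deg_c - exp_c) ** 2 / exp_c
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "deg_a": deg_a,
        "deg_c": deg_c,
        "ratio": deg_a / deg_c if deg_c else np.inf,
        "expected_a": exp_a,
        "expected_c": exp_c,
        "chi2": float(chi2),
        "p_value": p,
    }


def node_fold_change(
    expr: ExpressionMatrix,
    network: nx.Graph,
    deg_table: pd.DataFrame,
    ref_cluster: str,
    other_cluster: str,
) -> pd.DataFrame:
    """Pooled per-node expression fold-change over DEG-mapped orthologs.

    For each reaction node, genes whose ortholog ID belongs to the node AND
    that are called DEG in the comparison contribute their FPKM; the node
    statistic is log2(sum FPKM in other_cluster / sum in WEAm-style
    reference). Colors: red (> 0), blue (< 0), grey (no DEG-mapped genes or
    both sums zero). A zero denominator with nonzero numerator is flagged
    infinite and colored red.
    """
    if expr.ortholog is None:
        raise ValueError("expression matrix has no ortholog map")
    ref_acc = expr.accessions_of(ref_cluster)
    oth_acc = expr.accessions_of(other_cluster)
    deg_genes = set(deg_table.index[deg_table["call"] != "ns"])
    orth_to_genes = {}
    for gene, orth in expr.ortholog.items():
        if orth is not None and not (isinstance(orth, float) and np.isnan(orth)):
            orth_to_genes.setdefault(orth, []).append(gene)
    rows = []
    for node in network.nodes:
        members = network.nodes[node].get("orthologs", [])
        genes = [
            g
            for o in members
            for g in orth_to_genes.get(o, [])
            if g in deg_genes and g in expr.fpkm.index
        ]
        if not genes:
            rows.append((node, np.nan, "grey", 0))
            continue
        num = float(expr.fpkm.loc[genes, oth_acc].to_numpy().sum())
        den = float(expr.fpkm.loc[genes, ref_acc].to_numpy().sum())
        if den == 0 and num == 0:
            rows.append((node, np.nan, "grey", len(genes)))
        elif den == 0:
            log.warning("node %s: zero reference expression, infinite fold", node)
            rows.append((node, np.inf, "red", len(genes)))
        else:
            fc = float(np.log2(num / den)) if num > 0 else -np.inf
            color = "red" if fc > 0 else ("blue" if fc < 0 else "grey")
            rows.append((node, fc, color, len(genes)))
    out = pd.DataFrame(rows, columns=["node", "fold_change", "color", "n_genes"])
    return out.set_index("node")


def local_clustering(network: nx.Graph, node=None):
    """Local clustering coefficient(s): 2T / (k (k - 1)), 0 for degree < 2."""
    if node is not None:
        return float(nx.clustering(network, node))
    return {n: float(v) for n, v in nx.clustering(network).items()}
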