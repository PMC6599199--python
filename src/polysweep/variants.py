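"""VCF ingestion, the SNP filter cascade, sub-genome partition, allele counts.

The filter cascade mirrors a common RNA-seq population-genomics workflow:
strict depth (> 10) and mapping-quality (> 30) cutoffs, a genotyping-rate
cutoff, MAF >= 5 %, and an optional restriction to synonymous and non-coding
sites (annotation is consumed from the INFO FC field, never computed).
Two presets are exposed: ``group1`` (call rate > 0.5, no class filter, the
set used for diversity and the sweep scan) and ``group2`` (call rate > 0.9
plus the class filter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "AlleleCounts",
    "read_vcf",
    "write_vcf",
    "filter_variants",
    "partition_subgenome",
    "allele_counts",
    "FILTER_PRESETS",
]

log = logging.getLogger(__name__)

FILTER_PRESETS = {
    "group1": dict(min_call_rate=0.5, classes=None),
    "group2": dict(min_call_rate=0.9, classes=("synonymous", "noncoding")),
}


@dataclass
class VariantTable:
    """Biallelic SNPs with site metadata and diploid genotypes.

    sites: DataFrame with columns chrom, pos (0-based), ref, alt, depth,
    mapq, func_class — sorted by (chrom, pos), unique positions per chrom.
    genotypes: int8 array (n_sites, n_samples, 2) with -1 for missing alleles.
    phased: bool array (n_sites, n_samples).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list
    phased: np.ndarray = None
    dropped: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.phased is None:
            self.phased = np.ones(self.genotypes.shape[:2], dtype=bool)
        self.sites = self.sites.reset_index(drop=True)
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos) in variant table")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take(self, mask_or_idx) -> "VariantTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            sites=self.sites.iloc[idx],
            genotypes=self.genotypes[idx],
            samples=self.samples,
            phased=self.phased[idx],
            dropped=dict(self.dropped),
        )

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def haplotypes(self, sample_idx=None) -> np.ndarray:
        """Flatten genotypes to a (n_sites, 2*n_samples) haplotype matrix."""
        gt = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        return gt.reshape(gt.shape[0], -1)

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and self.sites.reset_index(drop=True).equals(
                other.sites.reset_index(drop=True)
            )
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phased, other.phased)
        )


@dataclass
class AlleleCounts:
    """Per-site allele counts for one sample group.

    m: alt-allele count; n: non-missing chromosomes; n_het / n_called:
    heterozygote and called-diploid counts (needed by the F_ST estimator).
    """

    m: np.ndarray
    n: np.ndarray
    n_het: np.ndarray
    n_called: np.ndarray

    @property
    def p_hat(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.n > 0, self.m / np.maximum(self.n, 1), np.nan)

    def __len__(self) -> int:
        return len(self.m)


def read_vcf(path) -> VariantTable:
    """Read a VCF 4.x into a VariantTable.

    Multi-allelic and non-SNP records are dropped and counted in
    ``table.dropped``. Coordinates are converted to 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gts, phased_rows = [], [], []
    dropped = {"multiallelic": 0, "non_snp": 0}
    for v in vcf:
        if len(v.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.ALT[0] not in "ACGT":
            dropped["non_snp"] += 1
            continue
        info = dict(v.INFO)
        rows.append(
            (
                v.CHROM,
                v.POS - 1,
                v.REF,
                v.ALT[0],
                int(info.get("DP", 0)),
                # cyvcf2 hands INFO floats back as float32; recover the
                # shortest decimal so written values round-trip exactly
                float(str(np.float32(info.get("MQ", 0.0)))),
                str(info.get("FC", "other")),
            )
        )
        g = np.array([row[:2] for row in v.genotypes], dtype=np.int8)
        ph = np.array([bool(row[2]) for row in v.genotypes])
        gts.append(g)
        phased_rows.append(ph)
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "depth", "mapq", "func_class"]
    )
    genotypes = (
        np.stack(gts) if gts else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    phased = (
        np.stack(phased_rows) if phased_rows else np.empty((0, len(samples)), bool)
    )
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    t = VariantTable(
        sites=sites.iloc[order],
        genotypes=genotypes[order],
        samples=samples,
        phased=phased[order],
        dropped=dropped,
    )
    if dropped["multiallelic"] or dropped["non_snp"]:
        log.info("read_vcf dropped records: %s", dropped)
    return t


def write_vcf(t: VariantTable, path) -> None:
    """Write a VariantTable back to VCF 4.2 (text)."""
    contigs = list(dict.fromkeys(t.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Mapping depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##INFO=<ID=FC,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(t.samples)
            + "\n"
        )
        sites = t.sites
        for i in range(len(t)):
            row = sites.iloc[i]
            fields = []
            for s in range(t.n_samples):
                a, b = t.genotypes[i, s]
                sep = "|" if t.phased[i, s] else "/"
                fa = "." if a < 0 else str(int(a))
                fb = "." if b < 0 else str(int(b))
                fields.append(f"{fa}{sep}{fb}")
            info = (
                f"DP={int(row.depth)};MQ={float(row.mapq):g};FC={row.func_class}"
            )
            fh.write(
                f"{row.chrom}\t{int(row.pos) + 1}\t.\t{row.ref}\t{row.alt}\t.\t"
                f"PASS\t{info}\tGT\t" + "\t".join(fields) + "\n"
            )


def _pooled_maf(genotypes: np.ndarray) -> np.ndarray:
    alleles = genotypes.reshape(genotypes.shape[0], -1)
    called = alleles >= 0
    n = called.sum(axis=1)
    m = np.where(called, alleles, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, m / np.maximum(n, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def filter_variants(
    t: VariantTable,
    min_depth: float = 10,
    min_mq: float = 30,
    min_call_rate: float = 0.9,
    min_maf: float = 0.05,
    classes=("synonymous", "noncoding"),
    report: dict = None,
) -> VariantTable:
    """Apply the filter cascade; thresholds are strict (>) for depth/MQ/call
    rate and inclusive (>=) for MAF. classes=None skips the class filter.

    ``report`` (optional dict) receives per-rule removal counts.
    """
    sites = t.sites
    keep = np.ones(len(t), dtype=bool)
    stages = []
    stages.append(("depth", sites["depth"].to_numpy() > min_depth))
    stages.append(("mapq", sites["mapq"].to_numpy() > min_mq))
    called = (t.genotypes >= 0).all(axis=2)
    call_rate = called.mean(axis=1) if t.n_samples else np.ones(len(t))
    stages.append(("call_rate", call_rate > min_call_rate))
    stages.append(("maf", _pooled_maf(t.genotypes) >= min_maf))
    if classes is not None:
        stages.append(("func_class", sites["func_class"].isin(classes).to_numpy()))
    for name, mask in stages:
        removed = int(np.sum(keep & ~mask))
        if report is not None:
            report[name] = removed
        keep &= mask
    return t.take(keep)


def partition_subgenome(t: VariantTable) -> dict:
    """Split sites by sub-genome from the chromosome-name prefix.

    Returns {'A': table, 'C': table, 'unassigned': table}; the three parts
    are disjoint and conserve the site count.
    """
    chrom = t.sites["chrom"].astype(str)
    a = chrom.str.startswith("A").to_numpy()
    c = chrom.str.startswith("C").to_numpy()
    return {
        "A": t.take(a),
        "C": t.take(c & ~a),
        "unassigned": t.take(~a & ~c),
    }


def allele_counts(t: VariantTable, sample_groups: dict) -> dict:
    """Alt-allele counts per site for each named group of samples.

    Groups must be disjoint. Missing genotypes are excluded from n; a site
    with zero non-missing calls in a group gets n = 0.
    """
    seen = set()
    for name, members in sample_groups.items():
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"sample groups overlap: {sorted(overlap)}")
        seen |= set(members)
    out = {}
    for name, members in sample_groups.items():
        idx = t.sample_indices(members)
        gt = t.genotypes[:, idx]  # (sites, k, 2)
        allele_called = gt >= 0
        n = allele_called.sum(axis=(1, 2))
        m = np.where(allele_called, gt, 0).sum(axis=(1, 2))
        dip_called = allele_called.all(axis=2)
        het = dip_called & (gt[..., 0] != gt[..., 1])
        out[name] = AlleleCounts(
            m=m.astype(np.int64),
            n=n.astype(np.int64),
            n_het=het.sum(axis=1).astype(np.int64),
            n_called=dip_called.sum(axis=1).astype(np.int64),
        )
    return out
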