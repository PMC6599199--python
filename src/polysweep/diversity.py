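"""Windowed diversity and divergence statistics.

Nucleotide diversity pi is windowed by dividing the summed per-site pi by the
full window length in bp (invariant sites contribute zero to the numerator),
which is why values land on the 1e-5 scale typical of transcriptome-based
SNP sets. F_ST is the Weir-Cockerham (1984) estimator from diploid genotype
counts, windowed in its "weighted" form sum(a) / sum(a+b+c). LD decay is the
mean pairwise r^2 binned by physical distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import AlleleCounts
from .windows import WindowTrack, window_starts

__all__ = [
    "site_pi",
    "windowed_pi",
    "wc_components",
    "windowed_fst",
    "LDCurve",
    "ld_decay",
    "pi_ratio_track",
]


def site_pi(m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2*m*(n-m) / (n*(n-1)).

    This is the mean pairwise difference among the n sampled chromosomes;
    sites with n < 2 yield NaN and are skipped by the windowing.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * m * (n - m) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def _window_sum(positions, values, starts, size):
    """Sum `values` over sites falling in each window [s, s+size)."""
    order = np.argsort(positions, kind="stable")
    pos = np.asarray(positions)[order]
    val = np.asarray(values, dtype=float)[order]
    csum = np.concatenate([[0.0], np.cumsum(val)])
    ccnt = np.arange(len(pos) + 1)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + size, side="left")
    return csum[hi] - csum[lo], ccnt[hi] - ccnt[lo]


def windowed_pi(
    counts: AlleleCounts,
    positions: np.ndarray,
    chrom_length: int,
    chrom: str = "chr",
    window: int = 100_000,
    step: int = 25_000,
) -> WindowTrack:
    """Sliding-window pi: sum of site pi divided by the window length in bp."""
    pi = site_pi(counts.m, counts.n)
    ok = ~np.isnan(pi)
    starts = window_starts(chrom_length, window, step)
    total, n_sites = _window_sum(
        np.asarray(positions)[ok], pi[ok], starts, window
    )
    return WindowTrack(
        chrom=chrom,
        starts=starts,
        size=window,
        step=step,
        values=total / window,
        n_sites=n_sites,
    )


def wc_components(a_counts: AlleleCounts, b_counts: AlleleCounts):
    """Per-site Weir-Cockerham (1984) variance components for two populations.

    Computed from diploid genotype counts: sample sizes n_i (called diploids),
    allele frequencies p_i, and observed heterozygote frequencies h_i.
    Returns (a, b, c) arrays; sites where either population has < 1 called
    diploid, or the mean sample size is <= 1, are NaN.
    """
    n1 = a_counts.n_called.astype(float)
    n2 = b_counts.n_called.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = a_counts.m / np.maximum(a_counts.n, 1)
        p2 = b_counts.m / np.maximum(b_counts.n, 1)
        h1 = a_counts.n_het / np.maximum(n1, 1)
        h2 = b_counts.n_het / np.maximum(n2, 1)
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def windowed_fst(
    counts_a: AlleleCounts,
    counts_b: AlleleCounts,
    positions: np.ndarray,
    chrom_length: int,
    chrom: str = "chr",
    window: int = 100_000,
    step: int = 25_000,
) -> WindowTrack:
    """Windowed Weir-Cockerham F_ST: sum(a) / sum(a+b+c) per window.

    Windows whose denominator is zero (no usable sites, or all sites
    monomorphic across both populations) are flagged missing (NaN).
    """
    a, b, c = wc_components(counts_a, counts_b)
    ok = ~np.isnan(a)
    starts = window_starts(chrom_length, window, step)
    pos = np.asarray(positions)[ok]
    num, n_sites = _window_sum(pos, a[ok], starts, window)
    den, _ = _window_sum(pos, (a + b + c)[ok], starts, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return WindowTrack(
        chrom=chrom, starts=starts, size=window, step=step,
        values=values, n_sites=n_sites,
    )


@dataclass
class LDCurve:
    """Mean pairwise r^2 binned by physical distance."""

    bin_edges: np.ndarray  # length n_bins + 1, covering (0, max_dist]
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _site_filters_haploid(hap, min_maf):
    p = hap.mean(axis=1)
    maf = np.minimum(p, 1 - p)
    return maf >= min_maf


def ld_decay(
    matrix: np.ndarray,
    positions: np.ndarray,
    max_dist: int = 3_000_000,
    min_maf: float = 0.05,
    max_het: float = 0.88,
    max_miss: float = 0.25,
    bin_size: int = 10_000,
    phased: bool = True,
) -> LDCurve:
    """LD-decay curve: mean r^2 against pairwise distance.

    phased=True expects a (n_sites, n_haplotypes) 0/1 matrix and computes the
    haplotype D-based r^2 (the squared allelic correlation). phased=False
    expects diploid dosages (0/1/2, -1 missing) and uses the genotype-dosage
    correlation (Rogers-Huff style). Site filters: MAF >= min_maf, observed
    heterozygosity <= max_het (unphased only), missingness <= max_miss.
    Monomorphic members of a pair are skipped.
    """
    positions = np.asarray(positions)
    matrix = np.asarray(matrix, dtype=float)
    if phased:
        keep = _site_filters_haploid(matrix, min_maf)
        data = matrix
    else:
        miss = matrix < 0
        miss_rate = miss.mean(axis=1)
        data = np.where(miss, np.nan, matrix)
        with np.errstate(invalid="ignore"):
            p = np.nanmean(data, axis=1) / 2.0
            het = np.nanmean(data == 1, axis=1)
        maf = np.minimum(p, 1 - p)
        keep = (maf >= min_maf) & (het <= max_het) & (miss_rate <= max_miss)
    data = data[keep]
    pos = positions[keep]
    # center columns; correlation-based r^2 equals D^2/(pA qA pB qB) for
    # haploid 0/1 data
    n_bins = int(np.ceil(max_dist / bin_size))
    edges = np.arange(0, (n_bins + 1) * bin_size, bin_size, dtype=np.int64)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    std = np.nanstd(data, axis=1)
    for i in range(len(pos) - 1):
        if std[i] == 0:
            continue
        j_hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
        js = np.arange(i + 1, j_hi)
        js = js[std[js] > 0]
        if len(js) == 0:
            continue
        xi = data[i]
        block = data[js]
        if np.isnan(data).any():
            r2 = np.empty(len(js))
            for k, j in enumerate(js):
                ok = ~np.isnan(xi) & ~np.isnan(data[j])
                if ok.sum() < 2 or np.std(xi[ok]) == 0 or np.std(data[j][ok]) == 0:
                    r2[k] = np.nan
                    continue
                r2[k] = np.corrcoef(xi[ok], data[j][ok])[0, 1] ** 2
        else:
            xc = xi - xi.mean()
            bc = block - block.mean(axis=1, keepdims=True)
            cov = bc @ xc / len(xc)
            r2 = (cov / (std[i] * std[js])) ** 2
        dist = pos[js] - pos[i]
        bins = np.minimum((dist - 1) // bin_size, n_bins - 1)
        ok = ~np.isnan(r2) & (dist > 0)
        np.add.at(sums, bins[ok], r2[ok])
        np.add.at(counts, bins[ok], 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDCurve(bin_edges=edges, mean_r2=mean_r2, n_pairs=counts)


def pi_ratio_track(
    pi_ref: WindowTrack, pi_obj: WindowTrack, epsilon: float = None
) -> WindowTrack:
    """Per-window pi_ref / pi_obj with a pseudocount.

    Both tracks must be on the same window grid (the sweep-scan grid of
    20 kb windows / 10 kb step in the standard pipeline). epsilon defaults to
    half the smallest nonzero windowed pi across both tracks, which keeps
    ratios finite without disturbing their ranking. Windows with no sites in
    either population are flagged missing.
    """
    if not pi_ref.same_grid(pi_obj):
        raise ValueError("pi tracks are on different window grids")
    if epsilon is None:
        pool = np.concatenate([pi_ref.values, pi_obj.values])
        nz = pool[np.isfinite(pool) & (pool > 0)]
        epsilon = 0.5 * nz.min() if len(nz) else 1e-12
    values = (pi_ref.values + epsilon) / (pi_obj.values + epsilon)
    empty = (pi_ref.n_sites == 0) & (pi_obj.n_sites == 0)
    values = np.where(empty, np.nan, values)
    return WindowTrack(
        chrom=pi_ref.chrom,
        starts=pi_ref.starts,
        size=pi_ref.size,
        step=pi_ref.step,
        values=values,
        n_sites=pi_ref.n_sites + pi_obj.n_sites,
    )
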