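"""Candidate sweep-region calculus.

Grid-point scan scores are averaged into 20 kb / 10 kb sliding windows; the
top 20 % of windows are merged into regions wherever they overlap or are
step-adjacent; regions whose best window is in the top 5 % of region scores
are kept; a parallel pi-ratio track contributes its top-50 % windows merged
the same way; the final candidate set is the bp-level intersection of the
two. Quantiles are empirical with "higher" interpolation, pooled over all
chromosomes, and ties at the threshold are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import WindowTrack, window_starts

__all__ = [
    "RegionSet",
    "mean_score_track",
    "call_score_regions",
    "call_ratio_regions",
    "intersect_regions",
    "genes_in_regions",
]

_COLS = ["chrom", "start", "end", "region_score", "source"]


@dataclass
class RegionSet:
    """Sorted, non-overlapping genomic intervals with scores.

    0-based half-open coordinates; region_score is the maximum constituent
    window value (or the overlap-derived score after intersection).
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_COLS))

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        if len(df):
            if (df["end"] <= df["start"]).any():
                raise ValueError("regions must satisfy end > start")
            df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
            for chrom, grp in df.groupby("chrom"):
                if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                    raise ValueError(f"overlapping regions on {chrom}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum()) if len(self.df) else 0

    def to_bed(self, path) -> None:
        self.df[["chrom", "start", "end"]].to_csv(
            path, sep="\t", index=False, header=False
        )

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "RegionSet":
        return cls(pd.read_csv(path, sep="\t"))


def mean_score_track(
    score_track: pd.DataFrame,
    chrom_length: int = None,
    window: int = 20_000,
    step: int = 10_000,
) -> WindowTrack:
    """Mean grid-point score per sliding window; empty windows are missing.

    score_track: DataFrame with columns chrom, pos, score (one chromosome).
    """
    chroms = score_track["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("mean_score_track expects a single chromosome")
    pos = score_track["pos"].to_numpy()
    val = score_track["score"].to_numpy(dtype=float)
    ok = np.isfinite(val)
    pos, val = pos[ok], val[ok]
    if chrom_length is None:
        chrom_length = int(pos.max()) + 1 if len(pos) else 1
    starts = window_starts(chrom_length, window, step)
    order = np.argsort(pos, kind="stable")
    pos, val = pos[order], val[order]
    csum = np.concatenate([[0.0], np.cumsum(val)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    n = hi - lo
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    return WindowTrack(
        chrom=str(chroms[0]), starts=starts, size=window, step=step,
        values=means, n_sites=n,
    )


def _quantile_threshold(values: np.ndarray, q_top: float) -> float:
    """Value such that the top q_top fraction (ties included) is selected."""
    return float(np.quantile(values, 1.0 - q_top, method="higher"))


def _merge_selected(track: WindowTrack, selected: np.ndarray, source: str):
    """Merge selected windows that overlap or are step-adjacent into regions."""
    rows = []
    starts = track.starts[selected]
    ends = track.ends[selected]
    vals = track.values[selected]
    cur = None  # [region_start, region_end, region_score]
    last_start = None
    for s, e, v in zip(starts, ends, vals):
        if cur is None:
            cur = [s, e, v]
        elif s < cur[1] or s == last_start + track.step:
            cur[1] = max(cur[1], e)
            cur[2] = max(cur[2], v)
        else:
            rows.append(cur)
            cur = [s, e, v]
        last_start = s
    if cur is not None:
        rows.append(cur)
    return [
        {"chrom": track.chrom, "start": int(s), "end": int(e),
         "region_score": float(v), "source": source}
        for s, e, v in rows
    ]


def _pool_tracks(tracks):
    if isinstance(tracks, WindowTrack):
        return [tracks]
    return list(tracks)


def call_score_regions(
    tracks, window_q: float = 0.20, region_q: float = 0.05, source: str = "xpclr"
) -> RegionSet:
    """Two-stage percentile region caller for mean-score tracks.

    Stage 1: windows with value >= the genome-wide (1 - window_q) empirical
    quantile are selected and merged. Stage 2: merged regions whose score
    (max window value) is >= the (1 - region_q) quantile of region scores are
    returned. Accepts one WindowTrack or a list (one per chromosome).
    """
    tracks = _pool_tracks(tracks)
    pooled = np.concatenate([t.values[np.isfinite(t.values)] for t in tracks])
    if len(pooled) == 0:
        return RegionSet()
    thr = _quantile_threshold(pooled, window_q)
    rows = []
    for t in tracks:
        sel = np.isfinite(t.values) & (t.values >= thr)
        rows.extend(_merge_selected(t, sel, source))
    if not rows:
        return RegionSet()
    df = pd.DataFrame(rows)
    thr2 = _quantile_threshold(df["region_score"].to_numpy(), region_q)
    return RegionSet(df[df["region_score"] >= thr2])


def call_ratio_regions(
    tracks, ratio_q: float = 0.50, source: str = "pi_ratio"
) -> RegionSet:
    """Single-stage percentile caller (top ratio_q windows, merged)."""
    tracks = _pool_tracks(tracks)
    pooled = np.concatenate([t.values[np.isfinite(t.values)] for t in tracks])
    if len(pooled) == 0:
        return RegionSet()
    thr = _quantile_threshold(pooled, ratio_q)
    rows = []
    for t in tracks:
        sel = np.isfinite(t.values) & (t.values >= thr)
        rows.extend(_merge_selected(t, sel, source))
    return RegionSet(pd.DataFrame(rows)) if rows else RegionSet()


def intersect_regions(a: RegionSet, b: RegionSet):
    """bp-level intersection of two region sets.

    Returns (RegionSet, overlap_fraction) where overlap_fraction is the
    fraction of regions of `a` overlapping at least one region of `b` — the
    cross-validation statistic between the score-based and the
    diversity-ratio-based callers.
    """
    rows = []
    hit = np.zeros(len(a), dtype=bool)
    for chrom in sorted(set(a.df["chrom"]) | set(b.df["chrom"])):
        da = a.df[a.df["chrom"] == chrom]
        db = b.df[b.df["chrom"] == chrom]
        for i, ra in da.iterrows():
            for _, rb in db.iterrows():
                s = max(ra["start"], rb["start"])
                e = min(ra["end"], rb["end"])
                if e > s:
                    hit[a.df.index.get_loc(i)] = True
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": int(s),
                            "end": int(e),
                            "region_score": float(ra["region_score"]),
                            "source": "intersection",
                        }
                    )
    frac = float(hit.mean()) if len(a) else 0.0
    if not rows:
        return RegionSet(), frac
    # merge any touching fragments produced by multiple b-overlaps
    df = pd.DataFrame(rows).sort_values(["chrom", "start"])
    merged = []
    for _, r in df.iterrows():
        if (
            merged
            and merged[-1]["chrom"] == r["chrom"]
            and r["start"] < merged[-1]["end"]
        ):
            merged[-1]["end"] = max(merged[-1]["end"], r["end"])
            merged[-1]["region_score"] = max(
                merged[-1]["region_score"], r["region_score"]
            )
        else:
            merged.append(dict(r))
    return RegionSet(pd.DataFrame(merged)), frac


def genes_in_regions(regions: RegionSet, annotation: pd.DataFrame):
    """Genes overlapping each region by >= 1 bp (half-open intervals).

    annotation: DataFrame indexed by gene with columns chrom, start, end.
    Returns (per-region list of gene lists, de-duplicated genome-wide list).
    """
    per_region = []
    seen = {}
    for _, r in regions.df.iterrows():
        sub = annotation[annotation["chrom"] == r["chrom"]]
        ov = sub[(sub["start"] < r["end"]) & (sub["end"] > r["start"])]
        genes = list(ov.index)
        per_region.append(genes)
        for g in genes:
            seen.setdefault(g, None)
    return per_region, list(seen)
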