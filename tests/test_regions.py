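"""Region calculus against enumerate-sort-merge oracles and boundary rules."""

import numpy as np
import pandas as pd
import pytest

import polysweep as ps
from polysweep.regions import RegionSet
from polysweep.windows import WindowTrack


def track(values, chrom="A01", size=20_000, step=10_000, starts=None):
    values = np.asarray(values, dtype=float)
    if starts is None:
        starts = np.arange(len(values)) * step
    return WindowTrack(
        chrom=chrom, starts=starts, size=size, step=step, values=values,
        n_sites=np.ones(len(values), int),
    )


def brute_call_score_regions(values, step, size, window_q, region_q):
    """Independent enumerate-sort-merge implementation (one chromosome)."""
    vals = [v for v in values if np.isfinite(v)]
    thr = np.quantile(vals, 1 - window_q, method="higher")
    sel = [
        (i * step, i * step + size, v)
        for i, v in enumerate(values)
        if np.isfinite(v) and v >= thr
    ]
    regions = []
    for s, e, v in sel:
        if regions and (s < regions[-1][1] or s == regions[-1][3] + step):
            regions[-1] = [
                regions[-1][0], max(regions[-1][1], e), max(regions[-1][2], v), s
            ]
        else:
            regions.append([s, e, v, s])
    if not regions:
        return []
    thr2 = np.quantile([r[2] for r in regions], 1 - region_q, method="higher")
    return [(r[0], r[1], r[2]) for r in regions if r[2] >= thr2]


class TestMeanScoreTrack:
    def test_constant_score(self):
        df = pd.DataFrame(
            {"chrom": "A01", "pos": np.arange(0, 100_000, 2_000), "score": 3.5}
        )
        t = ps.mean_score_track(df, chrom_length=100_000)
        assert np.allclose(t.values[np.isfinite(t.values)], 3.5)

    def test_single_grid_point(self):
        df = pd.DataFrame({"chrom": "A01", "pos": [15_000], "score": [7.0]})
        t = ps.mean_score_track(df, chrom_length=40_000)
        # point at 15 kb falls in windows starting at 0 and 10 kb
        assert t.values[0] == 7.0 and t.values[1] == 7.0
        assert np.isnan(t.values[2])

    def test_matches_brute_force(self, rng):
        pos = np.sort(rng.choice(300_000, 30, replace=False))
        score = rng.exponential(5, 30)
        df = pd.DataFrame({"chrom": "A01", "pos": pos, "score": score})
        t = ps.mean_score_track(df, chrom_length=300_000)
        for i, start in enumerate(t.starts):
            inside = score[(pos >= start) & (pos < start + 20_000)]
            if len(inside):
                assert t.values[i] == pytest.approx(inside.mean())
            else:
                assert np.isnan(t.values[i])


class TestCallScoreRegions:
    def test_all_equal_selects_everything(self):
        t = track([2.0] * 9)
        rs = ps.call_score_regions(t)
        assert len(rs) == 1
        assert rs.df.loc[0, "start"] == 0
        assert rs.df.loc[0, "end"] == 100_000

    def test_empty_track_empty_set(self):
        rs = ps.call_score_regions(track([np.nan, np.nan]))
        assert len(rs) == 0

    def test_nine_window_toy_matches_oracle(self):
        values = [1, 2, 9, 8, 1, 1, 7, 1, 1]
        rs = ps.call_score_regions(track(values), window_q=0.20, region_q=0.05)
        expected = brute_call_score_regions(values, 10_000, 20_000, 0.20, 0.05)
        assert len(rs) == len(expected)
        for (_, row), (s, e, v) in zip(rs.df.iterrows(), expected):
            assert (row["start"], row["end"]) == (s, e)
            assert row["region_score"] == pytest.approx(v)

    def test_random_toys_match_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 60))
            values = rng.exponential(1.0, n)
            values[rng.random(n) < 0.2] = np.nan
            if not np.isfinite(values).any():
                continue
            rs = ps.call_score_regions(track(values), 0.3, 0.25)
            expected = brute_call_score_regions(values, 10_000, 20_000, 0.3, 0.25)
            got = [
                (r["start"], r["end"]) for _, r in rs.df.iterrows()
            ]
            assert got == [(s, e) for s, e, _ in expected]

    def test_monotone_transform_invariance(self, rng):
        values = rng.exponential(1.0, 40)
        a = ps.call_score_regions(track(values), 0.2, 0.05)
        b = ps.call_score_regions(track(np.log1p(values)), 0.2, 0.05)
        assert a.df[["start", "end"]].equals(b.df[["start", "end"]])

    def test_gap_of_missing_window_breaks_region(self):
        # windows 0 and 2 selected, window 1 missing: regions [0,20k) [20k,40k)
        # abut but do not merge across the missing window
        values = [5.0, np.nan, 5.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        rs = ps.call_ratio_regions(track(values), ratio_q=0.2)
        assert len(rs) == 2
        assert list(rs.df["start"]) == [0, 20_000]


class TestRatioAndIntersect:
    def test_all_equal_single_region_per_chromosome(self):
        rs = ps.call_ratio_regions([track([1.0] * 5, "A01"), track([1.0] * 5, "C02")])
        assert len(rs) == 2
        assert set(rs.df["chrom"]) == {"A01", "C02"}

    def test_alternating_matches_merge_rule(self):
        # every other window selected; 20 kb windows at 10 kb step overlap,
        # so runs of two selected windows merge through the shared 10 kb
        values = [9, 0, 9, 0, 9, 0]
        rs = ps.call_ratio_regions(track(values), ratio_q=0.5)
        assert [tuple(r) for r in rs.df[["start", "end"]].to_numpy()] == [
            (0, 20_000), (20_000, 40_000), (40_000, 60_000)
        ]

    def test_disjoint_intersection_empty(self):
        a = RegionSet(pd.DataFrame(
            [{"chrom": "A01", "start": 0, "end": 10_000,
              "region_score": 1.0, "source": "x"}]
        ))
        b = RegionSet(pd.DataFrame(
            [{"chrom": "A01", "start": 50_000, "end": 60_000,
              "region_score": 1.0, "source": "y"}]
        ))
        inter, frac = ps.intersect_regions(a, b)
        assert len(inter) == 0 and frac == 0.0

    def test_half_open_boundary_arithmetic(self):
        a = RegionSet(pd.DataFrame(
            [{"chrom": "A01", "start": 0, "end": 30_000,
              "region_score": 2.0, "source": "x"}]
        ))
        b = RegionSet(pd.DataFrame(
            [{"chrom": "A01", "start": 20_000, "end": 50_000,
              "region_score": 1.0, "source": "y"}]
        ))
        inter, frac = ps.intersect_regions(a, b)
        assert [tuple(r) for r in inter.df[["start", "end"]].to_numpy()] == [
            (20_000, 30_000)
        ]
        assert frac == 1.0

    def test_random_sets_match_brute_force(self, rng):
        def random_set(seed):
            r = np.random.default_rng(seed)
            starts = np.sort(r.choice(50, 8, replace=False)) * 10_000
            ends = starts + r.integers(1, 3, 8) * 10_000
            keep = np.concatenate([[True], starts[1:] >= ends[:-1]])
            return RegionSet(pd.DataFrame({
                "chrom": "A01", "start": starts[keep], "end": ends[keep],
                "region_score": r.random(keep.sum()), "source": "t",
            }))

        for seed in range(10):
            a, b = random_set(seed), random_set(seed + 100)
            inter, frac = ps.intersect_regions(a, b)
            # brute force: bp-level membership
            cover_a = np.zeros(600_000, bool)
            cover_b = np.zeros(600_000, bool)
            for _, r in a.df.iterrows():
                cover_a[r["start"]:r["end"]] = True
            for _, r in b.df.iterrows():
                cover_b[r["start"]:r["end"]] = True
            both = cover_a & cover_b
            got = np.zeros(600_000, bool)
            for _, r in inter.df.iterrows():
                got[r["start"]:r["end"]] = True
            assert np.array_equal(got, both)
            n_hit = sum(
                bool(both[r["start"]:r["end"]].any()) for _, r in a.df.iterrows()
            )
            assert frac == pytest.approx(n_hit / len(a))

    def test_final_regions_contained_in_score_regions(self, rng):
        # set containment: intersecting with the ratio regions never adds bp
        a = ps.call_score_regions(track(rng.exponential(1, 50)), 0.2, 0.05)
        b = ps.call_ratio_regions(track(rng.exponential(1, 50)), 0.5)
        inter, _ = ps.intersect_regions(a, b)
        assert inter.total_bp() <= a.total_bp()


class TestGenesInRegions:
    @pytest.fixture
    def annotation(self):
        return pd.DataFrame(
            {
                "chrom": ["A01", "A01", "A01", "C01"],
                "start": [100, 5_000, 20_000, 100],
                "end": [900, 9_000, 21_000, 900],
            },
            index=["g1", "g2", "g3", "g4"],
        )

    def test_overlap_and_boundary(self, annotation):
        rs = RegionSet(pd.DataFrame(
            [{"chrom": "A01", "start": 0, "end": 20_000,
              "region_score": 1.0, "source": "x"}]
        ))
        per_region, dedup = ps.genes_in_regions(rs, annotation)
        # g3 starts exactly at the half-open region end: excluded
        assert per_region[0] == ["g1", "g2"]
        assert dedup == ["g1", "g2"]

    def test_twenty_gene_toy_matches_brute_force(self, rng):
        ann = pd.DataFrame(
            {
                "chrom": "A01",
                "start": rng.choice(100_000, 20, replace=False),
            },
            index=[f"g{i}" for i in range(20)],
        )
        ann["end"] = ann["start"] + rng.integers(500, 5_000, 20)
        rs = RegionSet(pd.DataFrame([
            {"chrom": "A01", "start": 10_000, "end": 30_000,
             "region_score": 1.0, "source": "x"},
            {"chrom": "A01", "start": 60_000, "end": 80_000,
             "region_score": 2.0, "source": "x"},
        ]))
        per_region, dedup = ps.genes_in_regions(rs, ann)
        for genes, (rs_, re_) in zip(per_region, [(10_000, 30_000), (60_000, 80_000)]):
            expected = [
                g for g in ann.index
                if ann.loc[g, "start"] < re_ and ann.loc[g, "end"] > rs_
            ]
            assert genes == expected
        assert len(dedup) == len(set(dedup))
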