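"""Composite-likelihood sweep scan and candidate-region calling.

Simulates a sweep, estimates the drift scale, runs the XP-CLR-style scan,
averages scores into 20 kb / 10 kb windows, calls top-20 % -> top-5 % score
regions and top-50 % pi-ratio regions, and intersects them into the final
candidate set.
"""

import numpy as np

import polysweep as ps
import polysweep.xpclr as xp
from polysweep.variants import AlleleCounts


def counts(hap):
    m = hap.sum(axis=1)
    gt = hap.reshape(hap.shape[0], -1, 2)
    return AlleleCounts(
        m=m, n=np.full(len(m), hap.shape[1]),
        n_het=(gt[..., 0] != gt[..., 1]).sum(axis=1),
        n_called=np.full(len(m), hap.shape[1] // 2),
    )


cfg = ps.SimConfig(n_ref=60, n_obj=60, chrom_length=1_000_000, n_snps=5_000,
                   omega=0.1, seed=3)
pair = ps.simulate_neutral_pair(cfg)
spec = ps.SweepSpec(position=500_000, sigma=0.004)
swept = ps.implant_sweep(pair.hap_obj, pair.positions, pair.genetic_map, spec, 4)

cr, co = counts(pair.hap_ref), counts(swept)
model = xp.estimate_omega(cr, co)
print(f"estimated drift scale omega = {model.omega:.3f}")

score = xp.xpclr_scan(cr, co, swept, pair.positions, pair.genetic_map,
                      xp.ScanParams(seed=0), model)
peak = score.loc[score["score"].idxmax()]
print(f"scan peak: {int(peak.pos):,} bp (score {peak.score:.1f}, "
      f"true site 500,000 bp)")

mean_track = ps.mean_score_track(score, cfg.chrom_length)
score_regions = ps.call_score_regions(mean_track)

pi_ref = ps.windowed_pi(cr, pair.positions, cfg.chrom_length,
                        window=20_000, step=10_000)
pi_obj = ps.windowed_pi(co, pair.positions, cfg.chrom_length,
                        window=20_000, step=10_000)
ratio_regions = ps.call_ratio_regions(ps.pi_ratio_track(pi_ref, pi_obj))

final, overlap = ps.intersect_regions(score_regions, ratio_regions)
print(f"score regions: {len(score_regions)}, pi-ratio regions: "
      f"{len(ratio_regions)}, intersected: {len(final)}")
print(f"fraction of score regions confirmed by the pi-ratio track: {overlap:.2f}")
for _, r in final.df.iterrows():
    mark = " <-- contains the implanted sweep" if r.start <= 500_000 < r.end else ""
    print(f"  {r.chrom}:{r.start:,}-{r.end:,}  score {r.region_score:.1f}{mark}")
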