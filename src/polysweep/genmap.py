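"""Genetic maps: bp <-> Morgan conversion.

Scan window sizes and sweep footprints are parameterised in Morgans, so every
scan needs a map. A linear map at a constant cM/Mb rate is the default used by
the simulator; arbitrary piecewise-linear maps can be loaded from a two-column
TSV (pos_bp, cM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "linear_map"]


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear genetic map for one chromosome.

    Parameters
    ----------
    pos_bp : ndarray
        Strictly increasing physical anchor positions (bp).
    cm : ndarray
        Map positions in centiMorgans at the anchors; non-decreasing.
    """

    pos_bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.pos_bp, dtype=float)
        cm = np.asarray(self.cm, dtype=float)
        if pos.ndim != 1 or pos.shape != cm.shape or pos.size < 2:
            raise ValueError("map needs >=2 (pos_bp, cM) anchor pairs")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("cM must be non-decreasing")
        object.__setattr__(self, "pos_bp", pos)
        object.__setattr__(self, "cm", cm)

    def morgans(self, pos):
        """Map physical position(s) in bp to Morgans (linear interpolation).

        Positions outside the anchor range are extrapolated with the rate of
        the terminal segment.
        """
        pos = np.asarray(pos, dtype=float)
        if np.any(pos < self.pos_bp[0] - 1) or np.any(pos > self.pos_bp[-1] + 1):
            # allow 1 bp slack for rounding; beyond that extrapolate linearly
            pass
        cm = np.interp(pos, self.pos_bp, self.cm)
        # linear extrapolation beyond anchors (np.interp clamps)
        lo, hi = self.pos_bp[0], self.pos_bp[-1]
        rate_lo = (self.cm[1] - self.cm[0]) / (self.pos_bp[1] - self.pos_bp[0])
        rate_hi = (self.cm[-1] - self.cm[-2]) / (self.pos_bp[-1] - self.pos_bp[-2])
        cm = np.where(pos < lo, self.cm[0] + (pos - lo) * rate_lo, cm)
        cm = np.where(pos > hi, self.cm[-1] + (pos - hi) * rate_hi, cm)
        return cm / 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos_bp": self.pos_bp.astype(int), "cM": self.cm})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        return cls(df["pos_bp"].to_numpy(), df["cM"].to_numpy())


def linear_map(chrom_length: int, rate_cm_per_mb: float = 1.0) -> GeneticMap:
    """Constant-rate map over [0, chrom_length]."""
    if chrom_length <= 0 or rate_cm_per_mb < 0:
        raise ValueError("chrom_length must be >0 and rate >=0")
    end_cm = rate_cm_per_mb * chrom_length / 1e6
    return GeneticMap(np.array([0.0, float(chrom_length)]), np.array([0.0, end_cm]))
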