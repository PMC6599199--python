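"""Sliding-window tracks on 0-based half-open genomic intervals."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WindowTrack", "window_starts"]


def window_starts(length: int, size: int, step: int) -> np.ndarray:
    """Starts of sliding windows [s, s+size) with s < length."""
    if size <= 0 or step <= 0 or length <= 0:
        raise ValueError("length, size and step must be positive")
    return np.arange(0, length, step, dtype=np.int64)


@dataclass
class WindowTrack:
    """Per-window statistic on a fixed sliding-window grid.

    Windows are 0-based half-open [start, start+size), constant size and step.
    ``values`` is NaN where the window is flagged missing; ``n_sites`` counts
    the variant sites that contributed to each window.
    """

    chrom: str
    starts: np.ndarray
    size: int
    step: int
    values: np.ndarray
    n_sites: np.ndarray = field(default=None)

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.n_sites is None:
            self.n_sites = np.zeros_like(self.starts)
        self.n_sites = np.asarray(self.n_sites, dtype=np.int64)
        if not (len(self.starts) == len(self.values) == len(self.n_sites)):
            raise ValueError("starts/values/n_sites length mismatch")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("window starts must be strictly increasing")

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.size

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.size == other.size
            and self.step == other.step
            and len(self.starts) == len(other.starts)
            and bool(np.all(self.starts == other.starts))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "value": self.values,
                "n_sites": self.n_sites,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "WindowTrack":
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise ValueError("empty track file")
        starts = df["start"].to_numpy()
        size = int(df["end"].iloc[0] - df["start"].iloc[0])
        step = int(starts[1] - starts[0]) if len(starts) > 1 else size
        return cls(
            chrom=str(df["chrom"].iloc[0]),
            starts=starts,
            size=size,
            step=step,
            values=df["value"].to_numpy(),
            n_sites=df["n_sites"].to_numpy(),
        )
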