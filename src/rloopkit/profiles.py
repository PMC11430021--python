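"""Metaprofiles: external signal averaged over windows centered on intervals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import read_bedgraph

__all__ = ["SignalTrack", "MetaMatrix", "signal_matrix"]


class SignalTrack:
    """Piecewise-constant signal (bedGraph semantics), zero where undefined."""

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = {}
        self._cum = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, np.int64)
            ends = np.asarray(ends, np.int64)
            values = np.asarray(values, float)
            if not np.isfinite(values).all():
                raise ValueError(f"non-finite signal value on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping signal intervals on {chrom}")
            self._data[chrom] = (starts, ends, values)
            areas = values * (ends - starts)
            self._cum[chrom] = np.concatenate(([0.0], np.cumsum(areas)))

    @classmethod
    def from_bedgraph(cls, path) -> "SignalTrack":
        return cls(read_bedgraph(path))

    def integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the track over (-inf, x) for an array of positions."""
        if chrom not in self._data:
            return np.zeros(np.shape(x), float)
        starts, ends, values = self._data[chrom]
        cum = self._cum[chrom]
        x = np.asarray(x, float)
        k = np.searchsorted(starts, x, side="right") - 1
        kk = np.clip(k, 0, len(starts) - 1)
        inside = np.clip(x - starts[kk], 0, ends[kk] - starts[kk])
        return np.where(k >= 0, cum[kk] + values[kk] * inside, 0.0)

    def window_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Length-weighted means over consecutive [edges[i], edges[i+1]) bins."""
        ig = self.integral(chrom, edges)
        widths = np.diff(edges)
        return np.diff(ig) / widths


@dataclass
class MetaMatrix:
    matrix: np.ndarray   # rows = centers, cols = n_bins
    mean: np.ndarray
    n_used: int
    flank: int
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        width = 2 * self.flank / self.n_bins
        centers = -self.flank + (np.arange(self.n_bins) + 0.5) * width
        df = pd.DataFrame(self.matrix,
                          columns=[f"bin_{i}" for i in range(self.n_bins)])
        df.attrs["bin_centers"] = centers
        return df

    def mean_frame(self) -> pd.DataFrame:
        width = 2 * self.flank / self.n_bins
        return pd.DataFrame({
            "offset": -self.flank + (np.arange(self.n_bins) + 0.5) * width,
            "mean_signal": self.mean,
        })


def signal_matrix(track: SignalTrack, centers, flank: int = 2500,
                  n_bins: int = 100, orient_by_strand: bool = False) -> MetaMatrix:
    """Signal matrix over [-flank, +flank) windows around interval midpoints.

    Bin values are length-weighted track means; regions beyond chromosome
    or track bounds contribute zero (rows are kept, not dropped). With
    ``orient_by_strand``, rows for '-'-strand centers are reversed.
    """
    centers = list(centers)
    if not centers:
        raise ValueError("no centers given")
    if n_bins % 2:
        raise ValueError("n_bins must be even")
    if flank <= 0:
        raise ValueError("flank must be positive")
    rows = np.zeros((len(centers), n_bins))
    width = 2.0 * flank / n_bins
    for i, c in enumerate(centers):
        mid = (c.start + c.end) // 2
        edges = mid - flank + width * np.arange(n_bins + 1)
        row = track.window_means(c.chrom, edges)
        strand = getattr(c, "strand", None)
        if orient_by_strand and strand == "-":
            row = row[::-1]
        rows[i] = row
    return MetaMatrix(rows, rows.mean(axis=0), len(centers), flank, n_bins)
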