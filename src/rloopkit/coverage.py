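"""Strand-split binned coverage and replicate PCA quality control.

Coverage is counted in fragment-bases: each fragment contributes its base
overlap to every bin it spans, on its own strand. This makes conservation
exactly testable — summing all bins recovers the clipped fragment lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Condition, FragmentSet, GenomeModel

__all__ = ["StrandedCoverage", "QCReport", "bin_coverage", "binned_bases",
           "coverage_matrix", "pca_qc", "scale_rows"]

STRANDS = ("+", "-")


def binned_bases(starts: np.ndarray, ends: np.ndarray, chrom_len: int, bin_width: int) -> np.ndarray:
    """Fragment-base counts per bin for one chromosome.

    Intervals are clipped to [0, chrom_len). Uses a difference-array depth
    profile summed into bins, so cost is O(n + chrom_len).
    """
    n_bins = -(-chrom_len // bin_width)  # ceil
    out = np.zeros(n_bins, dtype=np.float64)
    if len(starts) == 0:
        return out
    s = np.clip(np.asarray(starts, np.int64), 0, chrom_len)
    e = np.clip(np.asarray(ends, np.int64), 0, chrom_len)
    keep = e > s
    s, e = s[keep], e[keep]
    if s.size == 0:
        return out
    diff = np.bincount(s, minlength=chrom_len + 1).astype(np.int64)
    diff -= np.bincount(e, minlength=chrom_len + 1)
    depth = np.cumsum(diff[:-1])
    pad = n_bins * bin_width - chrom_len
    if pad:
        depth = np.concatenate([depth, np.zeros(pad, np.int64)])
    out[:] = depth.reshape(n_bins, bin_width).sum(axis=1)
    return out


@dataclass
class StrandedCoverage:
    """Binned fragment-base counts, one vector per (chrom, strand)."""

    sample_id: str
    condition: Condition
    bin_width: int
    data: dict[tuple[str, str], np.ndarray]  # (chrom, strand) -> bin vector
    total_fragment_bases: float

    def vector(self, chrom_order: list[str]) -> np.ndarray:
        """Concatenate bins: chroms in given order, '+' block then '-' block."""
        blocks = [self.data[(c, strand)] for strand in STRANDS for c in chrom_order]
        return np.concatenate(blocks)


def bin_coverage(frags: FragmentSet, genome: GenomeModel, bin_width: int = 500) -> StrandedCoverage:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    for chrom in np.unique(frags.chrom):
        if chrom not in genome.chrom_sizes:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
    data: dict[tuple[str, str], np.ndarray] = {}
    total = 0.0
    for chrom, chrom_len in genome.chrom_sizes.items():
        cmask = frags.chrom == chrom
        for strand in STRANDS:
            m = cmask & (frags.strand == strand)
            vec = binned_bases(frags.start[m], frags.end[m], chrom_len, bin_width)
            data[(chrom, strand)] = vec
            total += vec.sum()
    return StrandedCoverage(frags.sample_id, frags.condition, bin_width, data, total)


def coverage_matrix(samples: list[StrandedCoverage], genome: GenomeModel) -> np.ndarray:
    """Stack samples into a (bins x samples) matrix in fixed row order."""
    if not samples:
        raise ValueError("no samples")
    bw = samples[0].bin_width
    if any(s.bin_width != bw for s in samples):
        raise ValueError("samples have mismatched bin_width")
    keys = set(samples[0].data)
    if any(set(s.data) != keys for s in samples):
        raise ValueError("samples cover different genomes")
    order = genome.chroms
    return np.column_stack([s.vector(order) for s in samples])


def scale_rows(matrix: np.ndarray, drop_constant: bool = True) -> np.ndarray:
    """Standardize each row to zero mean, unit variance (sd with ddof=1,
    matching the conventional per-feature scaling). Constant rows dropped."""
    matrix = np.asarray(matrix, float)
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    informative = sd[:, 0] > 0
    if drop_constant:
        matrix, mean, sd = matrix[informative], mean[informative], sd[informative]
    if matrix.shape[0] == 0:
        raise ValueError("degenerate matrix: no rows with nonzero variance")
    return (matrix - mean) / sd


@dataclass
class QCReport:
    sample_ids: list[str]
    conditions: list[Condition]
    coords: np.ndarray          # samples x 2 (PC1, PC2)
    variance_fractions: np.ndarray
    groups_separate: bool

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "condition": [c.value for c in self.conditions],
            "PC1": self.coords[:, 0],
            "PC2": self.coords[:, 1],
        })


def pca_qc(matrix: np.ndarray, conditions: list[Condition],
           sample_ids: list[str] | None = None) -> QCReport:
    """PCA on row-scaled coverage; flags whether DRIP and RNASEH samples
    occupy disjoint PC1 ranges (sign-invariant)."""
    matrix = np.asarray(matrix, float)
    n_samples = matrix.shape[1]
    if n_samples < 3:
        raise ValueError("pca_qc requires at least 3 samples")
    if len(conditions) != n_samples:
        raise ValueError("conditions length mismatch")
    conditions = [Condition(c) for c in conditions]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    scaled = scale_rows(matrix)
    # observations = samples; rows are already centered per feature
    x = scaled.T
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords_all = u * s
    var = s ** 2
    var_frac = var / var.sum() if var.sum() > 0 else var
    k = min(2, coords_all.shape[1])
    coords = np.zeros((n_samples, 2))
    coords[:, :k] = coords_all[:, :k]
    drip = np.array([c is Condition.DRIP for c in conditions])
    separate = False
    if drip.any() and (~drip).any():
        pc1 = coords[:, 0]
        separate = bool(pc1[drip].min() > pc1[~drip].max() or pc1[drip].max() < pc1[~drip].min())
    return QCReport(list(sample_ids), conditions, coords, var_frac[:2], separate)
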