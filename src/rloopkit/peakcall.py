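"""Treatment-vs-control enrichment calling on sliding windows.

Each window is scored with a Poisson upper-tail test against a local
background rate estimated from the control sample: the maximum of the
genome-wide control rate and control rates measured in nested windows
(1/5/10 kb by default) centered on the tested window, rescaled to the
treatment depth, plus a pseudocount. Window p-values are BH-adjusted
genome-wide; significant windows are linked across small gaps into narrow
and broad peaks.

Counts enter the test as fragment-equivalents: fragment-bases in the
window divided by the sample's mean fragment length, rounded — so the
Poisson unit is "fragments in window".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc

from .coverage import binned_bases
from .io import FragmentSet, GenomeModel

__all__ = ["CallerParams", "Peak", "poisson_sf", "local_lambda", "bh_qvalues",
           "call_peaks", "link_intervals", "pool_fragments", "write_narrowpeak"]


@dataclass(frozen=True)
class CallerParams:
    window: int = 200
    step: int = 100
    local_windows: tuple[int, ...] = (1000, 5000, 10000)
    pseudocount: float = 0.5
    q_narrow: float = 0.05
    q_broad: float = 0.10
    link_gap_narrow: int = 200
    link_gap_broad: int = 800
    min_peak_len: int = 200

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if self.window % self.step:
            raise ValueError("step must divide window")
        for q in (self.q_narrow, self.q_broad):
            if not (0 < q < 1):
                raise ValueError("q thresholds must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    strand: str = "."
    summit: int = 0           # offset from start
    max_fold: float = 0.0
    p: float = 1.0
    q: float = 1.0
    mode: str = "narrow"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak start must be < end")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must be in [0, 1]")


def poisson_sf(t, lam):
    """P(X >= t) for X ~ Poisson(lam), stable for large t.

    Uses the identity P(X >= t) = gammainc(t, lam) (regularized lower
    incomplete gamma), which is evaluated in log space internally.
    Accepts scalars or arrays; t must be non-negative integers.
    """
    t_arr = np.asarray(t)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("lambda must be >= 0")
    if np.any(t_arr < 0) or not np.all(np.equal(np.mod(t_arr, 1), 0)):
        raise ValueError("t must be a non-negative integer")
    t_f = t_arr.astype(float)
    with np.errstate(invalid="ignore"):
        out = np.where(t_f == 0, 1.0, gammainc(np.maximum(t_f, 1.0), lam_arr))
    if np.isscalar(t) and np.isscalar(lam):
        return float(out)
    return out


def local_lambda(window: int, local_bases: dict[int, float], genome_rate: float,
                 depth_ratio: float, mean_frag_len: float, pseudocount: float = 0.5) -> float:
    """Background rate for one tested window.

    ``local_bases`` maps nested-window size L -> control fragment-bases in
    the L-sized window centered on the tested window. Each candidate is
    lambda_L = (bases / mean_frag_len) * (window / L) * depth_ratio; the
    genome-wide candidate is genome_rate * window * depth_ratio with
    ``genome_rate`` in fragments/bp. Result is the max plus pseudocount.
    """
    if depth_ratio <= 0:
        raise ValueError("depth_ratio must be > 0")
    if mean_frag_len <= 0:
        if pseudocount == 0:
            raise ValueError("empty control with zero pseudocount")
        return pseudocount
    cands = [genome_rate * window * depth_ratio]
    for L, bases in local_bases.items():
        cands.append((bases / mean_frag_len) * (window / L) * depth_ratio)
    lam = max(cands) + pseudocount
    if lam == 0:
        raise ValueError("empty control with zero pseudocount")
    return lam


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pool_fragments(sets: list[FragmentSet], sample_id: str = "pooled") -> FragmentSet:
    """Merge several samples into one (the merged-control operation)."""
    if not sets:
        raise ValueError("nothing to pool")
    if len(sets) == 1:
        return sets[0]
    return FragmentSet(
        sample_id, sets[0].condition,
        np.concatenate([s.chrom for s in sets]),
        np.concatenate([s.start for s in sets]),
        np.concatenate([s.end for s in sets]),
        np.concatenate([s.strand for s in sets]),
    )


def _strand_filter(frags: FragmentSet, strand_mode: str) -> FragmentSet:
    if strand_mode == "both":
        return frags
    if strand_mode == "plus_only":
        return frags.on_strand("+")
    if strand_mode == "minus_only":
        return frags.on_strand("-")
    raise ValueError(f"unknown strand_mode {strand_mode!r}")


def call_peaks(
    treatment: FragmentSet,
    control: FragmentSet | list[FragmentSet],
    genome: GenomeModel,
    params: CallerParams = CallerParams(),
    strand_mode: str = "both",
    strand_label: str = ".",
) -> list[Peak]:
    """Score sliding windows, BH-adjust genome-wide, link into peaks.

    Returns narrow peaks (q <= q_narrow, gaps <= link_gap_narrow) and broad
    peaks (q <= q_broad, gaps <= link_gap_broad) together; each Peak carries
    its mode and the best member-window p/q.
    """
    if isinstance(control, list):
        control = pool_fragments(control, "merged_control")
    treatment = _strand_filter(treatment, strand_mode)
    control = _strand_filter(control, strand_mode)

    w, step = params.window, params.step
    if all(length < w for length in genome.chrom_sizes.values()):
        raise ValueError(f"no chromosome is at least one window ({w} bp) long")
    if len(treatment) == 0:
        warnings.warn(f"treatment {treatment.sample_id!r} has no fragments; no peaks called")
        return []

    lt = treatment.mean_length
    lc = control.mean_length
    n_t, n_c = len(treatment), len(control)
    if n_c == 0 and params.pseudocount == 0:
        raise ValueError("empty control with zero pseudocount")
    r = (n_t / n_c) if n_c else 1.0
    genome_rate = n_c / genome.total_length  # control fragments per bp

    k = w // step
    chrom_names: list[str] = []
    win_starts: list[np.ndarray] = []
    t_counts: list[np.ndarray] = []
    lam_all: list[np.ndarray] = []

    for chrom, chrom_len in genome.chrom_sizes.items():
        if chrom_len < w:
            continue
        tmask = treatment.chrom == chrom
        cmask = control.chrom == chrom
        tb = binned_bases(treatment.start[tmask], treatment.end[tmask], chrom_len, step)
        cb = binned_bases(control.start[cmask], control.end[cmask], chrom_len, step)
        pt = np.concatenate(([0.0], np.cumsum(tb)))
        pc = np.concatenate(([0.0], np.cumsum(cb)))
        n_win = (chrom_len - w) // step + 1
        j = np.arange(n_win)
        t_bases = pt[j + k] - pt[j]
        t_cnt = np.rint(t_bases / lt).astype(np.int64)

        lam = np.full(n_win, genome_rate * w * r)
        if lc > 0:
            nb = len(cb)
            for L in params.local_windows:
                hw = max(1, round(L / (2 * step)))
                lo = np.clip(j + k // 2 - hw, 0, nb)
                hi = np.clip(j + k // 2 + hw, 0, nb)
                bases = pc[hi] - pc[lo]
                lam = np.maximum(lam, (bases / lc) * (w / L) * r)
        lam = lam + params.pseudocount
        if np.any(lam <= 0):
            raise ValueError("empty control with zero pseudocount")

        chrom_names.append(chrom)
        win_starts.append(j * step)
        t_counts.append(t_cnt)
        lam_all.append(lam)

    p_concat = poisson_sf(np.concatenate(t_counts), np.concatenate(lam_all))
    q_concat = bh_qvalues(p_concat)

    peaks: list[Peak] = []
    offset = 0
    for chrom, starts, t_cnt, lam in zip(chrom_names, win_starts, t_counts, lam_all):
        n = len(starts)
        p = p_concat[offset:offset + n]
        q = q_concat[offset:offset + n]
        offset += n
        for mode, q_thr, gap in (("narrow", params.q_narrow, params.link_gap_narrow),
                                 ("broad", params.q_broad, params.link_gap_broad)):
            sig = np.flatnonzero(q <= q_thr)
            if sig.size == 0:
                continue
            fold = t_cnt[sig] / lam[sig]
            peaks.extend(_link_significant(chrom, starts[sig], w, p[sig], q[sig],
                                           t_cnt[sig], fold, gap, params.min_peak_len,
                                           mode, strand_label))
    peaks.sort(key=lambda pk: (pk.chrom, pk.start, pk.mode))
    return peaks


def _link_significant(chrom, starts, w, p, q, counts, fold, gap, min_len, mode, strand):
    """Merge significant windows whose gap is <= ``gap`` into Peak records."""
    out: list[Peak] = []
    i = 0
    n = len(starts)
    while i < n:
        j = i
        end = starts[i] + w
        while j + 1 < n and starts[j + 1] - end <= gap:
            j += 1
            end = starts[j] + w
        members = slice(i, j + 1)
        start = int(starts[i])
        end = int(starts[j] + w)
        if end - start >= min_len:
            best = members.start + int(np.argmax(counts[members]))
            summit = int(starts[best] + w // 2 - start)
            out.append(Peak(chrom, start, end, strand, summit,
                            float(np.max(fold[members])),
                            float(np.min(p[members])), float(np.min(q[members])), mode))
        i = j + 1
    return out


def link_intervals(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Merge (start, end) intervals whose separation is <= gap. Idempotent."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def write_narrowpeak(peaks: list[Peak], path) -> None:
    """BED6+4: name, score = int(-10*log10 q) capped at 1000, strand, fold,
    -log10 p, -log10 q, summit offset."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            q = max(pk.q, 1e-300)
            p = max(pk.p, 1e-300)
            score = min(int(round(-10 * np.log10(q))), 1000)
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.mode}_peak_{i + 1}\t{score}\t"
                     f"{pk.strand}\t{pk.max_fold:.5g}\t{-np.log10(p):.5g}\t"
                     f"{-np.log10(q):.5g}\t{pk.summit}\n")
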