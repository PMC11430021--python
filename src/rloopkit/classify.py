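"""Replicate consensus and stranded/unstranded classification.

A consensus R-loop is the union-merge of qualifying peaks (q <= 0.001 in
the narrow or broad call) supported by at least 3 distinct samples. Strand
specificity is then assessed per consensus loop by a second round of calls
in which one strand's fragments are the treatment and the opposite strand's
fragments are the control; a loop overlapped by qualifying strand peaks of
exactly one strand (same support filter) is "stranded", otherwise
"unstranded".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Condition, FragmentSet, GenomeModel
from .peakcall import CallerParams, Peak, call_peaks

__all__ = ["RLoopCall", "consensus_rloops", "call_strand_enrichment",
           "classify_strandedness", "write_rloops_bed", "rloops_to_frame"]


@dataclass
class RLoopCall:
    chrom: str
    start: int
    end: int
    rloop_class: str | None = None  # "stranded" | "unstranded" | None (unset)
    strand: str | None = None       # "+" | "-" | None
    n_supporting_samples: int = 0
    support_modes: dict[int, str] = field(default_factory=dict)  # sample idx -> narrow/broad/both
    best_q: float = 1.0

    def __post_init__(self) -> None:
        if self.rloop_class == "stranded" and self.strand not in ("+", "-"):
            raise ValueError("stranded call requires a strand")
        if self.rloop_class == "unstranded" and self.strand is not None:
            raise ValueError("unstranded call must have strand None")


def _qualifying(peaks: list[Peak], q_max: float) -> list[Peak]:
    return [p for p in peaks if p.q <= q_max]


def consensus_rloops(per_sample_peaks: list[list[Peak]], min_support: int = 3,
                     q_max: float = 0.001) -> list[RLoopCall]:
    """Union-merge qualifying peaks across samples; keep merged regions with
    >=1 bp overlap from qualifying peaks of at least ``min_support`` distinct
    samples. Classes are left unset."""
    n_samples = len(per_sample_peaks)
    if min_support > n_samples:
        raise ValueError(f"min_support={min_support} exceeds {n_samples} samples")
    qual = [_qualifying(peaks, q_max) for peaks in per_sample_peaks]
    by_chrom: dict[str, list[tuple[int, int, int, Peak]]] = {}
    for si, peaks in enumerate(qual):
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end, si, p))
    out: list[RLoopCall] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0], t[1]))
        # union-merge (bookended intervals merge)
        clusters: list[list[tuple[int, int, int, Peak]]] = []
        cur_end = None
        for it in items:
            if cur_end is None or it[0] > cur_end:
                clusters.append([it])
                cur_end = it[1]
            else:
                clusters[-1].append(it)
                cur_end = max(cur_end, it[1])
        for cluster in clusters:
            start = min(it[0] for it in cluster)
            end = max(it[1] for it in cluster)
            # support requires a true >=1 bp overlap with the merged region,
            # which holds for every member by construction of the cluster
            supporters: dict[int, set[str]] = {}
            best_q = 1.0
            for s, e, si, p in cluster:
                supporters.setdefault(si, set()).add(p.mode)
                best_q = min(best_q, p.q)
            if len(supporters) < min_support:
                continue
            modes = {si: ("both" if len(m) > 1 else next(iter(m)))
                     for si, m in supporters.items()}
            out.append(RLoopCall(chrom, start, end, None, None,
                                 len(supporters), modes, best_q))
    return out


def call_strand_enrichment(sample: FragmentSet, genome: GenomeModel,
                           params: CallerParams = CallerParams()) -> list[Peak]:
    """Two caller runs on one DRIP sample: '+' fragments vs '-' fragments as
    control, then the reverse. Emitted peaks carry the treatment strand."""
    if sample.condition is Condition.RNASEH:
        raise ValueError("strand enrichment is assessed on DRIP samples only")
    import warnings
    plus = sample.on_strand("+")
    minus = sample.on_strand("-")
    if len(plus) == 0 or len(minus) == 0:
        warnings.warn(f"sample {sample.sample_id!r}: one strand has no fragments; "
                      "proceeding with pseudocount-only background")
    peaks: list[Peak] = []
    if len(plus):
        peaks += call_peaks(plus, minus, genome, params, strand_label="+")
    if len(minus):
        peaks += call_peaks(minus, plus, genome, params, strand_label="-")
    peaks.sort(key=lambda p: (p.chrom, p.start, p.strand, p.mode))
    return peaks


def _overlap_supports(loop: RLoopCall, peaks_by_chrom: dict[str, list[tuple[int, int, int]]]) -> set[int]:
    """Sample indices whose peaks overlap the loop by >=1 bp."""
    hits = set()
    for s, e, si in peaks_by_chrom.get(loop.chrom, ()):
        if s < loop.end and loop.start < e:
            hits.add(si)
    return hits


def classify_strandedness(consensus: list[RLoopCall],
                          per_sample_strand_peaks: list[list[Peak]],
                          min_support: int = 3, q_max: float = 0.001) -> list[RLoopCall]:
    """Set the class of every consensus loop.

    Stranded iff qualifying strand peaks from >= min_support distinct samples
    of exactly one strand overlap the loop by >=1 bp. If both strands qualify
    independently, the loop is unstranded (no single dominating strand).
    Returns new RLoopCall records; the partition is exhaustive.
    """
    index: dict[str, dict[str, list[tuple[int, int, int]]]] = {"+": {}, "-": {}}
    for si, peaks in enumerate(per_sample_strand_peaks):
        for p in _qualifying(peaks, q_max):
            if p.strand not in ("+", "-"):
                raise ValueError("strand peaks must carry '+' or '-'")
            index[p.strand].setdefault(p.chrom, []).append((p.start, p.end, si))
    out: list[RLoopCall] = []
    for loop in consensus:
        qualified = [s for s in ("+", "-")
                     if len(_overlap_supports(loop, index[s])) >= min_support]
        if len(qualified) == 1:
            cls, strand = "stranded", qualified[0]
        else:
            cls, strand = "unstranded", None
        out.append(RLoopCall(loop.chrom, loop.start, loop.end, cls, strand,
                             loop.n_supporting_samples, dict(loop.support_modes),
                             loop.best_q))
    return out


def write_rloops_bed(rloops: list[RLoopCall], path) -> None:
    """BED6 with class in the name field; unstranded loops get strand '.'."""
    with open(path, "w") as fh:
        for i, rl in enumerate(rloops):
            strand = rl.strand or "."
            name = rl.rloop_class or "unclassified"
            q = max(rl.best_q, 1e-300)
            score = min(int(round(-10 * np.log10(q))), 1000)
            fh.write(f"{rl.chrom}\t{rl.start}\t{rl.end}\t{name}\t{score}\t{strand}\n")


def rloops_to_frame(rloops: list[RLoopCall]) -> pd.DataFrame:
    rows = []
    for rl in rloops:
        rows.append({
            "chrom": rl.chrom, "start": rl.start, "end": rl.end,
            "class": rl.rloop_class, "strand": rl.strand or ".",
            "n_supporting_samples": rl.n_supporting_samples,
            "support_modes": ";".join(f"{k}:{v}" for k, v in sorted(rl.support_modes.items())),
            "best_q": rl.best_q,
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "class", "strand",
                                       "n_supporting_samples", "support_modes", "best_q"])
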