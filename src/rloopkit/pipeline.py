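"""End-to-end orchestration shared by the CLI and programmatic callers."""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import (RLoopCall, call_strand_enrichment, classify_strandedness,
                       consensus_rloops)
from .io import Condition, FragmentSet, GenomeModel
from .peakcall import CallerParams, Peak, call_peaks, pool_fragments

__all__ = ["ConsensusParams", "call_and_classify"]


@dataclass(frozen=True)
class ConsensusParams:
    min_support: int = 3
    q_max: float = 0.001


def call_and_classify(
    genome: GenomeModel,
    samples: list[FragmentSet],
    caller: CallerParams = CallerParams(),
    consensus: ConsensusParams = ConsensusParams(),
):
    """Run the full caller: total calls per replicate against the merged
    control, replicate consensus, per-replicate strand-enrichment calls, and
    strandedness classification.

    Returns ``(rloops, per_sample_total_peaks, per_sample_strand_peaks)``.
    """
    drip = [s for s in samples if s.condition is Condition.DRIP]
    controls = [s for s in samples if s.condition is Condition.RNASEH]
    if not drip:
        raise ValueError("no DRIP samples")
    if not controls:
        raise ValueError("no RNASEH control samples")
    merged = pool_fragments(controls, "merged_control")

    total_peaks: list[list[Peak]] = [call_peaks(s, merged, genome, caller) for s in drip]
    loops = consensus_rloops(total_peaks, consensus.min_support, consensus.q_max)
    strand_peaks: list[list[Peak]] = [call_strand_enrichment(s, genome, caller) for s in drip]
    rloops: list[RLoopCall] = classify_strandedness(loops, strand_peaks,
                                                    consensus.min_support, consensus.q_max)
    return rloops, total_peaks, strand_peaks
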