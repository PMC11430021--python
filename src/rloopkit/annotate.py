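"""Genomic-feature assignment, observed/expected enrichment, gene associations.

The feature map partitions each chromosome base-by-base into one of
promoter_tss, exon, intron, downstream_tts, pseudogene, intergenic using a
fixed priority (listed order, highest first). Promoter windows are
[TSS-2500, TSS+500) and downstream windows [end-500, end+2500), both in
gene orientation and clipped at chromosome boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import RLoopCall
from .io import Gene, GenomeModel, IntervalRecord

__all__ = ["FEATURES", "FeatureMap", "EnrichmentRow", "build_feature_map",
           "assign_feature", "obs_exp_enrichment", "overlap_gene_classes",
           "gene_length_density", "promoter_window", "downstream_window"]

FEATURES = ["promoter_tss", "exon", "intron", "downstream_tts", "pseudogene", "intergenic"]
_IDX = {f: i for i, f in enumerate(FEATURES)}

PROMOTER_UP = 2500
PROMOTER_DOWN = 500
DOWNSTREAM_IN = 500
DOWNSTREAM_OUT = 2500


def promoter_window(gene: Gene) -> tuple[int, int]:
    """[-2.5 kb, +0.5 kb) around the TSS in gene orientation (unclipped)."""
    if gene.strand == "+":
        return gene.start - PROMOTER_UP, gene.start + PROMOTER_DOWN
    return gene.end - PROMOTER_DOWN, gene.end + PROMOTER_UP


def downstream_window(gene: Gene) -> tuple[int, int]:
    """[-0.5 kb, +2.5 kb) around the gene end in gene orientation (unclipped)."""
    if gene.strand == "+":
        return gene.end - DOWNSTREAM_IN, gene.end + DOWNSTREAM_OUT
    return gene.start - DOWNSTREAM_OUT, gene.start + DOWNSTREAM_IN


@dataclass
class FeatureMap:
    """Per-base feature labels (int8 codes into FEATURES) per chromosome."""

    labels: dict[str, np.ndarray]

    def label_at(self, chrom: str, pos: int) -> str:
        arr = self.labels.get(chrom)
        if arr is None or not (0 <= pos < len(arr)):
            return "intergenic"
        return FEATURES[arr[pos]]

    def feature_bp(self) -> dict[str, int]:
        counts = np.zeros(len(FEATURES), dtype=np.int64)
        for arr in self.labels.values():
            counts += np.bincount(arr, minlength=len(FEATURES))
        return {f: int(counts[i]) for f, i in _IDX.items()}

    def fractions(self) -> dict[str, float]:
        bp = self.feature_bp()
        total = sum(bp.values())
        return {f: bp[f] / total for f in FEATURES}


def build_feature_map(genome: GenomeModel,
                      exons: list[IntervalRecord] | None = None) -> FeatureMap:
    """Paint features in ascending priority so higher-priority labels win.

    Pseudogene bodies are labelled "pseudogene"; other gene bodies default
    to "intron" unless exon intervals are supplied. Promoter and downstream
    windows are computed for non-pseudogene genes. Windows running past a
    chromosome boundary are clipped, not rejected.
    """
    labels = {chrom: np.full(size, _IDX["intergenic"], dtype=np.int8)
              for chrom, size in genome.chrom_sizes.items()}

    def paint(chrom: str, start: int, end: int, feature: str) -> None:
        arr = labels[chrom]
        s, e = max(start, 0), min(end, len(arr))
        if s < e:
            arr[s:e] = _IDX[feature]

    pseudo = [g for g in genome.genes if g.biotype == "pseudogene"]
    regular = [g for g in genome.genes if g.biotype != "pseudogene"]

    for g in pseudo:
        paint(g.chrom, g.start, g.end, "pseudogene")
    for g in regular:
        paint(g.chrom, *downstream_window(g), "downstream_tts")
    for g in regular:
        paint(g.chrom, g.start, g.end, "intron")
    if exons:
        for ex in exons:
            paint(ex.chrom, ex.start, ex.end, "exon")
    for g in regular:
        paint(g.chrom, *promoter_window(g), "promoter_tss")
    return FeatureMap(labels)


def _midpoint(iv) -> tuple[str, int]:
    return iv.chrom, (iv.start + iv.end) // 2


def assign_feature(rloop, fmap: FeatureMap) -> str:
    """Label of the interval containing the R-loop midpoint."""
    chrom, mid = _midpoint(rloop)
    return fmap.label_at(chrom, mid)


@dataclass
class EnrichmentRow:
    rloop_class: str
    feature: str
    observed: int
    expected: float
    ratio: float
    ci_low: float
    ci_high: float


def obs_exp_enrichment(rloops: list[RLoopCall], fmap: FeatureMap,
                       genome: GenomeModel, n_boot: int = 1000,
                       seed: int = 0) -> list[EnrichmentRow]:
    """Observed/expected feature counts per R-loop class.

    expected(f) = n_class * genome_fraction(f); the CI is the 2.5/97.5
    percentile of ratios obtained by dropping the same number of midpoints
    uniformly over the genome ``n_boot`` times.
    """
    if not rloops:
        raise ValueError("no R-loops to annotate")
    rng = np.random.default_rng(seed)
    fractions = fmap.fractions()
    chroms = genome.chroms
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(sizes)))
    total = int(cum[-1])

    classes = sorted({rl.rloop_class or "unclassified" for rl in rloops})
    rows: list[EnrichmentRow] = []
    for cls in classes:
        members = [rl for rl in rloops if (rl.rloop_class or "unclassified") == cls]
        n = len(members)
        observed = {f: 0 for f in FEATURES}
        for rl in members:
            observed[assign_feature(rl, fmap)] += 1
        # uniform-midpoint resamples, shared across features of this class
        boot_counts = np.zeros((n_boot, len(FEATURES)), dtype=np.int64)
        for b in range(n_boot):
            flat = rng.integers(0, total, size=n)
            ci = np.searchsorted(cum, flat, side="right") - 1
            labs = np.empty(n, dtype=np.int8)
            for k in range(len(chroms)):
                m = ci == k
                if m.any():
                    labs[m] = fmap.labels[chroms[k]][flat[m] - cum[k]]
            boot_counts[b] = np.bincount(labs, minlength=len(FEATURES))
        for f in FEATURES:
            frac = fractions[f]
            expected = n * frac
            ratio = observed[f] / expected if expected > 0 else float("nan")
            if expected > 0:
                boot_ratio = boot_counts[:, _IDX[f]] / expected
                ci_low, ci_high = np.percentile(boot_ratio, [2.5, 97.5])
            else:
                ci_low = ci_high = float("nan")
            rows.append(EnrichmentRow(cls, f, observed[f], expected, ratio,
                                      float(ci_low), float(ci_high)))
    return rows


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "class": r.rloop_class, "feature": r.feature, "observed": r.observed,
        "expected": r.expected, "ratio": r.ratio,
        "ci_low": r.ci_low, "ci_high": r.ci_high,
    } for r in rows])


def _extended_span(gene: Gene) -> tuple[int, int]:
    """Gene span unioned with its promoter and downstream windows."""
    ps, pe = promoter_window(gene)
    ds, de = downstream_window(gene)
    return min(gene.start, ps, ds), max(gene.end, pe, de)


def _expression_strata(genes: list[Gene], floor: float = 1.0) -> pd.DataFrame:
    expressed = [g for g in genes if g.expression > floor]
    if not expressed:
        raise ValueError(f"no genes with expression > {floor}")
    expr = np.array([g.expression for g in expressed])
    order = np.argsort(expr, kind="stable")
    stratum = np.empty(len(expressed), dtype=object)
    n = len(expressed)
    thirds = [order[:n // 3] if n >= 3 else order,
              order[n // 3: 2 * n // 3],
              order[2 * n // 3:]]
    for name, idx in zip(("low", "mid", "high"), thirds):
        stratum[idx] = name
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in expressed],
        "chrom": [g.chrom for g in expressed],
        "start": [g.start for g in expressed],
        "end": [g.end for g in expressed],
        "strand": [g.strand for g in expressed],
        "length": [g.length for g in expressed],
        "expression": expr,
        "stratum": stratum,
        "ext_start": [_extended_span(g)[0] for g in expressed],
        "ext_end": [_extended_span(g)[1] for g in expressed],
    })


def _flag_overlaps(df: pd.DataFrame, intervals, col: str) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    flags = np.zeros(len(df), dtype=bool)
    for i, (chrom, s, e) in enumerate(zip(df["chrom"], df["ext_start"], df["ext_end"])):
        flags[i] = any(ps < e and s < pe for ps, pe in by_chrom.get(chrom, ()))
    df[col] = flags


def overlap_gene_classes(genome: GenomeModel, rloops: list[RLoopCall],
                         factor_peaks: list[IntervalRecord] | None = None,
                         expression_floor: float = 1.0) -> pd.DataFrame:
    """Per-gene R-loop/factor overlap flags with low/mid/high expression strata.

    Overlap is >=1 bp against the gene span extended by the promoter and
    downstream windows. Only genes with expression above the floor are kept.
    """
    df = _expression_strata(genome.genes, expression_floor)
    stranded = [rl for rl in rloops if rl.rloop_class == "stranded"]
    unstranded = [rl for rl in rloops if rl.rloop_class == "unstranded"]
    _flag_overlaps(df, stranded, "has_stranded")
    _flag_overlaps(df, unstranded, "has_unstranded")
    if factor_peaks is not None:
        _flag_overlaps(df, factor_peaks, "has_factor_peak")
    return df.drop(columns=["ext_start", "ext_end"])


def stratum_proportions(gene_table: pd.DataFrame) -> pd.DataFrame:
    flag_cols = [c for c in gene_table.columns if c.startswith("has_")]
    return gene_table.groupby("stratum")[flag_cols].mean().reset_index()


def gene_length_density(genome: GenomeModel, rloops: list[RLoopCall],
                        expression_floor: float = 1.0) -> pd.DataFrame:
    """Per expressed gene: length, stratum, and which R-loop classes touch it
    (none / stranded_only / unstranded_only / both)."""
    df = _expression_strata(genome.genes, expression_floor)
    _flag_overlaps(df, [rl for rl in rloops if rl.rloop_class == "stranded"], "has_stranded")
    _flag_overlaps(df, [rl for rl in rloops if rl.rloop_class == "unstranded"], "has_unstranded")
    sets = np.select(
        [df["has_stranded"] & df["has_unstranded"],
         df["has_stranded"], df["has_unstranded"]],
        ["both", "stranded_only", "unstranded_only"], default="none")
    df["rloop_set"] = sets
    return df[["gene_id", "length", "expression", "stratum", "rloop_set"]]


def median_lengths_by_set(density_table: pd.DataFrame) -> dict[str, float]:
    return density_table.groupby("rloop_set")["length"].median().to_dict()
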