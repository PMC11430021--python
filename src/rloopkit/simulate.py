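"""Synthetic ssDRIP-seq cohorts with planted ground truth.

The generator plants stranded and unstranded R-loops on a small genome and
emits strand-split fragment sets for immunoprecipitated (DRIP) replicates
and nuclease-treated (RNASEH) controls. Controls carry background only.
All randomness flows from ``SimConfig.seed``; sample ``i`` of a cohort uses
``seed + i * 10007`` so replicates are independent yet reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .io import (
    Condition,
    FragmentSet,
    Gene,
    GenomeModel,
    write_chrom_sizes,
    write_fragments,
    write_gene_table,
)

__all__ = ["SimConfig", "TruthRLoop", "make_genome", "plant_rloops",
           "simulate_fragments", "simulate_cohort", "write_cohort"]

_SUBSEED_STRIDE = 10007


@dataclass(frozen=True)
class TruthRLoop:
    chrom: str
    start: int
    end: int
    true_class: str  # "stranded" | "unstranded"
    true_strand: str | None  # "+" | "-" | None (unstranded)
    enrichment_fold: float

    def __post_init__(self) -> None:
        if self.true_class not in ("stranded", "unstranded"):
            raise ValueError(f"bad true_class {self.true_class!r}")
        if (self.true_strand is None) != (self.true_class == "unstranded"):
            raise ValueError("true_strand must be None exactly for unstranded loops")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")


@dataclass
class SimConfig:
    """Knobs for one synthetic cohort.

    Defaults give a 5 Mb two-chromosome genome, 4 DRIP + 4 control samples,
    ~2e5 fragments per sample (mean length 250 bp) and 50 planted loops of
    each class at 10-fold enrichment.
    """

    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 3_000_000), ("chr2", 2_000_000)])
    n_genes: int = 300
    n_stranded: int = 50
    n_unstranded: int = 50
    fold: float = 10.0
    background_rate: float = 0.02  # fragments / bp / strand
    frag_len_mean: float = 250.0
    frag_len_sd: float = 50.0
    n_reps: int = 4
    n_controls: int = 4
    seed: int = 0
    placement_bias: str = "none"  # none | tss_stranded_tts_unstranded | long_genes
    loop_len_min: int = 800
    loop_len_max: int = 2000
    min_gene_len: int = 500

    def __post_init__(self) -> None:
        if not self.genome:
            raise ValueError("genome must be non-empty")
        for n in (self.n_genes, self.n_stranded, self.n_unstranded,
                  self.n_reps, self.n_controls):
            if n < 0:
                raise ValueError("counts must be >= 0")
        # fold == 1 is allowed as the null cohort: loops are planted but emit
        # no extra signal, giving a ground-truth-negative dataset
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.frag_len_mean <= 0:
            raise ValueError("frag_len_mean must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.placement_bias not in ("none", "tss_stranded_tts_unstranded", "long_genes"):
            raise ValueError(f"unknown placement_bias {self.placement_bias!r}")
        if not (0 < self.loop_len_min <= self.loop_len_max):
            raise ValueError("invalid loop length range")


class _Occupancy:
    """Per-chrom overlap bookkeeping for rejection-sampled placement."""

    def __init__(self) -> None:
        self._ivs: dict[str, list[tuple[int, int]]] = {}

    def collides(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self._ivs.get(chrom, ()))

    def add(self, chrom: str, start: int, end: int) -> None:
        self._ivs.setdefault(chrom, []).append((start, end))


def _choose_chrom(rng: np.random.Generator, genome: list[tuple[str, int]]) -> tuple[str, int]:
    lengths = np.array([l for _, l in genome], float)
    i = rng.choice(len(genome), p=lengths / lengths.sum())
    return genome[i]


def make_genome(cfg: SimConfig) -> GenomeModel:
    """Place non-overlapping genes with log-normal lengths and a low/mid/high
    expression mixture. Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    sizes = dict(cfg.genome)
    occ = _Occupancy()
    genes: list[Gene] = []
    max_tries = max(200 * cfg.n_genes, 1000)
    tries = 0
    # expression mixture components: roughly "off", mid, high (CPM-like)
    comp_mu = np.log([0.5, 5.0, 50.0])
    for i in range(cfg.n_genes):
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {cfg.n_genes} non-overlapping genes "
                    f"after {max_tries} attempts; genome too small")
            length = int(np.exp(rng.normal(np.log(4000), 0.6)))
            length = max(cfg.min_gene_len, length)
            chrom, chrom_len = _choose_chrom(rng, cfg.genome)
            if length >= chrom_len:
                continue
            start = int(rng.integers(0, chrom_len - length))
            if occ.collides(chrom, start, start + length):
                continue
            occ.add(chrom, start, start + length)
            break
        strand = "+" if rng.random() < 0.5 else "-"
        comp = rng.integers(0, 3)
        expression = float(np.exp(rng.normal(comp_mu[comp], 0.5)))
        biotype = "pseudogene" if rng.random() < 0.1 else (
            "other" if rng.random() < 0.1 else "protein_coding")
        genes.append(Gene(f"gene_{i:04d}", chrom, strand, start, start + length,
                          biotype, expression))
    genes.sort(key=lambda g: (list(sizes).index(g.chrom), g.start))
    return GenomeModel(sizes, genes)


def _place_loop(rng, cfg, genome, occ, center_hint=None, chrom_hint=None):
    """Draw one non-overlapping loop interval; returns (chrom, start, end)."""
    sizes = genome.chrom_sizes
    for _ in range(2000):
        length = int(rng.integers(cfg.loop_len_min, cfg.loop_len_max + 1))
        if center_hint is not None:
            chrom = chrom_hint
            center = int(center_hint + rng.normal(0, 400))
        else:
            chrom, chrom_len = _choose_chrom(rng, list(sizes.items()))
            center = int(rng.integers(0, chrom_len))
        chrom_len = sizes[chrom]
        start = max(0, center - length // 2)
        end = min(chrom_len, start + length)
        if end - start < cfg.loop_len_min // 2:
            continue
        if occ.collides(chrom, start, end):
            if center_hint is not None:
                return None  # caller picks a different host gene
            continue
        occ.add(chrom, start, end)
        return chrom, start, end
    raise RuntimeError("could not place R-loops without overlap; genome too crowded")


def plant_rloops(genome: GenomeModel, cfg: SimConfig) -> list[TruthRLoop]:
    """Plant ``n_stranded + n_unstranded`` disjoint truth loops.

    Bias modes:
      * ``none`` — uniform over the genome, stranded loops get a random strand.
      * ``tss_stranded_tts_unstranded`` — stranded loops near gene TSSs (strand
        = enriched/host-gene strand), unstranded loops downstream of gene ends.
      * ``long_genes`` — hosts drawn with probability proportional to gene
        length squared, loops inside gene bodies.
    """
    if cfg.placement_bias != "none" and not genome.genes:
        raise ValueError(f"placement_bias={cfg.placement_bias} requires genes")
    rng = np.random.default_rng(cfg.seed + 1)
    occ = _Occupancy()
    loops: list[TruthRLoop] = []

    def pick_gene(weights=None):
        idx = rng.choice(len(genome.genes), p=weights)
        return genome.genes[idx]

    lengths = np.array([g.length for g in genome.genes], float) if genome.genes else None
    long_w = lengths ** 2 / (lengths ** 2).sum() if lengths is not None and lengths.size else None

    for true_class, count in (("stranded", cfg.n_stranded), ("unstranded", cfg.n_unstranded)):
        placed = 0
        guard = 0
        while placed < count:
            guard += 1
            if guard > 200 * max(count, 1):
                raise RuntimeError("insufficient space to plant R-loops")
            if cfg.placement_bias == "none":
                spot = _place_loop(rng, cfg, genome, occ)
                strand = ("+" if rng.random() < 0.5 else "-") if true_class == "stranded" else None
            elif cfg.placement_bias == "tss_stranded_tts_unstranded":
                g = pick_gene()
                if true_class == "stranded":
                    hint = g.tss
                else:
                    off = int(abs(rng.normal(1500, 500)))
                    hint = g.tts + off if g.strand == "+" else g.tts - off
                hint = min(max(hint, 0), genome.chrom_sizes[g.chrom] - 1)
                spot = _place_loop(rng, cfg, genome, occ, center_hint=hint, chrom_hint=g.chrom)
                strand = g.strand if true_class == "stranded" else None
            else:  # long_genes
                g = pick_gene(long_w)
                hint = int(rng.integers(g.start, g.end))
                spot = _place_loop(rng, cfg, genome, occ, center_hint=hint, chrom_hint=g.chrom)
                strand = g.strand if true_class == "stranded" else None
            if spot is None:
                continue
            chrom, start, end = spot
            loops.append(TruthRLoop(chrom, start, end, true_class, strand, cfg.fold))
            placed += 1
    return loops


def _draw_lengths(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Fragment lengths ~ Normal(mean, sd) truncated to [50, 2*mean]."""
    if n == 0:
        return np.zeros(0, np.int64)
    lo, hi = 50.0, 2.0 * cfg.frag_len_mean
    a = (lo - cfg.frag_len_mean) / cfg.frag_len_sd
    b = (hi - cfg.frag_len_mean) / cfg.frag_len_sd
    vals = truncnorm.rvs(a, b, loc=cfg.frag_len_mean, scale=cfg.frag_len_sd,
                         size=n, random_state=rng)
    return np.maximum(np.rint(vals).astype(np.int64), 1)


def simulate_fragments(
    genome: GenomeModel,
    truth: list[TruthRLoop],
    cfg: SimConfig,
    condition: Condition,
    sample_index: int = 0,
    sample_id: str | None = None,
) -> FragmentSet:
    """Generate one sample's strand-split fragments.

    Background: per chromosome and per strand, Poisson(rate * length)
    fragments with uniform start positions. DRIP samples additionally get
    Poisson((fold - 1) * 2 * rate * loop_length) fragments per planted loop,
    midpoints uniform inside the loop — all on the enriched strand for
    stranded loops, split evenly in expectation for unstranded loops — so
    total in-loop coverage approaches ``fold`` times background. RNASEH
    samples carry background only.
    """
    condition = Condition(condition)
    rng = np.random.default_rng(cfg.seed + sample_index * _SUBSEED_STRIDE)
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    strands: list[np.ndarray] = []

    def emit(chrom: str, chrom_len: int, mids: np.ndarray, lens: np.ndarray, strand_col: np.ndarray):
        s = np.maximum(mids - lens // 2, 0)
        e = np.minimum(s + lens, chrom_len)
        s = np.minimum(s, e - 1)
        chroms.append(np.full(len(s), chrom, object))
        starts.append(s)
        ends.append(e)
        strands.append(strand_col)

    for chrom, chrom_len in genome.chrom_sizes.items():
        for strand in ("+", "-"):
            n = rng.poisson(cfg.background_rate * chrom_len)
            if n == 0:
                continue
            mids = rng.integers(0, chrom_len, size=n)
            lens = _draw_lengths(rng, n, cfg)
            emit(chrom, chrom_len, mids, lens, np.full(n, strand, object))

    if condition is Condition.DRIP:
        for loop in truth:
            lam = (loop.enrichment_fold - 1.0) * 2.0 * cfg.background_rate * (loop.end - loop.start)
            n = rng.poisson(lam)
            if n == 0:
                continue
            mids = rng.integers(loop.start, loop.end, size=n)
            lens = _draw_lengths(rng, n, cfg)
            if loop.true_class == "stranded":
                strand_col = np.full(n, loop.true_strand, object)
            else:
                strand_col = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
            emit(loop.chrom, genome.chrom_sizes[loop.chrom], mids, lens, strand_col)

    if not chroms:
        return FragmentSet.from_records(sample_id or f"sample_{sample_index}", condition, [])
    sid = sample_id or f"sample_{sample_index}"
    return FragmentSet(sid, condition, np.concatenate(chroms), np.concatenate(starts),
                       np.concatenate(ends), np.concatenate(strands))


def simulate_cohort(cfg: SimConfig, outdir: str | Path | None = None):
    """Build genome, truth and all sample FragmentSets; optionally write them.

    Returns ``(genome, truth, samples)`` with ``n_reps`` DRIP sets followed by
    ``n_controls`` RNASEH sets.
    """
    genome = make_genome(cfg)
    truth = plant_rloops(genome, cfg)
    samples: list[FragmentSet] = []
    for i in range(cfg.n_reps):
        samples.append(simulate_fragments(genome, truth, cfg, Condition.DRIP,
                                          sample_index=i, sample_id=f"drip_{i + 1}"))
    for j in range(cfg.n_controls):
        samples.append(simulate_fragments(genome, truth, cfg, Condition.RNASEH,
                                          sample_index=cfg.n_reps + j,
                                          sample_id=f"rnaseh_{j + 1}"))
    if outdir is not None:
        write_cohort(genome, truth, samples, outdir, cfg)
    return genome, truth, samples


def write_cohort(genome, truth, samples, outdir, cfg: SimConfig | None = None) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_chrom_sizes(genome.chrom_sizes, outdir / "genome.chrom.sizes")
    paths["chrom_sizes"] = str(outdir / "genome.chrom.sizes")
    write_gene_table(genome.genes, outdir / "genes.tsv")
    paths["genes"] = str(outdir / "genes.tsv")
    with open(outdir / "truth.bed", "w") as fh:
        for t in truth:
            strand = t.true_strand or "."
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.true_class}\t"
                     f"{t.enrichment_fold:g}\t{strand}\n")
    paths["truth"] = str(outdir / "truth.bed")
    for s in samples:
        p = outdir / f"{s.sample_id}.fragments.bed"
        write_fragments(s, p)
        paths[s.sample_id] = str(p)
    if cfg is not None:
        import json
        with open(outdir / "sim_config.json", "w") as fh:
            json.dump(asdict(cfg), fh, indent=2, sort_keys=True)
    return paths
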