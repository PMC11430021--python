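"""Genomic file formats and the core domain containers.

Everything internal is 0-based, half-open (BED convention). Fragments are
whole sequenced fragments, not individual reads; paired reads are assumed
to have been merged into one interval upstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Gene",
    "GenomeModel",
    "FragmentSet",
    "IntervalRecord",
    "read_chrom_sizes",
    "read_gene_table",
    "write_gene_table",
    "read_fragments",
    "write_fragments",
    "read_bed6",
    "write_bed6",
    "read_bedgraph",
    "write_bedgraph",
    "apply_blacklist",
]

_BIOTYPES = {"protein_coding", "pseudogene", "other"}


class Condition(str, enum.Enum):
    """Sample condition: immunoprecipitated or nuclease-treated control."""

    DRIP = "DRIP"
    RNASEH = "RNASEH"


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start in genome coordinates (end-1 side for '-' genes)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenomeModel:
    """Chromosome sizes plus the gene annotation used for feature windows."""

    chrom_sizes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {size}")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > self.chrom_sizes[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def validate_fragments(self, frags: "FragmentSet") -> None:
        """Raise if any fragment falls on an unknown chromosome or outside it."""
        for chrom in np.unique(frags.chrom):
            if chrom not in self.chrom_sizes:
                raise ValueError(f"fragment on unknown chromosome {chrom}")
            m = frags.chrom == chrom
            if frags.start[m].min(initial=0) < 0 or frags.end[m].max(initial=0) > self.chrom_sizes[chrom]:
                raise ValueError(f"fragment outside bounds of {chrom}")


class FragmentSet:
    """One sample's aligned fragments, stored as parallel numpy columns."""

    def __init__(
        self,
        sample_id: str,
        condition: Condition,
        chrom: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        strand: np.ndarray,
    ):
        n = len(chrom)
        if not (len(start) == len(end) == len(strand) == n):
            raise ValueError("fragment columns have mismatched lengths")
        self.sample_id = sample_id
        self.condition = Condition(condition)
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.strand = np.asarray(strand, dtype=object)
        if n:
            if (self.end <= self.start).any():
                raise ValueError("fragment with end <= start")
            bad = ~np.isin(self.strand, ("+", "-"))
            if bad.any():
                raise ValueError("fragment strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self):
        return iter(zip(self.chrom, self.start, self.end, self.strand))

    @classmethod
    def from_records(cls, sample_id, condition, records) -> "FragmentSet":
        records = list(records)
        if not records:
            return cls(sample_id, condition, np.empty(0, object), np.empty(0, np.int64),
                       np.empty(0, np.int64), np.empty(0, object))
        chrom, start, end, strand = zip(*records)
        return cls(sample_id, condition, np.array(chrom, object), np.array(start, np.int64),
                   np.array(end, np.int64), np.array(strand, object))

    def subset(self, mask: np.ndarray, sample_id: str | None = None) -> "FragmentSet":
        return FragmentSet(sample_id or self.sample_id, self.condition,
                           self.chrom[mask], self.start[mask], self.end[mask], self.strand[mask])

    def on_strand(self, strand: str) -> "FragmentSet":
        return self.subset(np.asarray(self.strand == strand),
                           sample_id=f"{self.sample_id}{strand}")

    @property
    def total_bases(self) -> int:
        return int((self.end - self.start).sum())

    @property
    def mean_length(self) -> float:
        if len(self) == 0:
            return 0.0
        return float((self.end - self.start).mean())


@dataclass(frozen=True)
class IntervalRecord:
    """A BED6 record."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


def _fmt_score(score: float) -> str:
    if float(score) == int(score):
        return str(int(score))
    return repr(float(score))


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column <chrom>\\t<length> table, order preserved."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


_GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "biotype", "expression"]


def read_gene_table(path) -> list[Gene]:
    """Read a headered gene TSV.

    Unknown biotypes collapse to "other"; missing expression becomes 0.
    Duplicate gene ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in _GENE_COLUMNS if c not in df.columns and c != "expression"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "expression" not in df.columns:
        df["expression"] = 0.0
    df["expression"] = df["expression"].fillna(0.0)
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        biotype = row.biotype if row.biotype in _BIOTYPES else "other"
        genes.append(Gene(row.gene_id, row.chrom, row.strand, int(row.start), int(row.end),
                          biotype, float(row.expression)))
    return genes


def write_gene_table(genes: list[Gene], path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.start, g.end, g.biotype, g.expression) for g in genes],
        columns=_GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_fragments(path, condition: Condition, sample_id: str | None = None) -> FragmentSet:
    """Read strand-split fragments from BED6. Strand is mandatory for this assay."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >=6 tab-separated fields")
            strand = parts[5]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: strand must be '+' or '-' (got {strand!r}); "
                    "unstranded fragments are not valid for this assay"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    sid = sample_id if sample_id is not None else Path(path).stem
    return FragmentSet(sid, condition,
                       np.array(chroms, object), np.array(starts, np.int64),
                       np.array(ends, np.int64), np.array(strands, object))


def write_fragments(frags: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(frags)):
            fh.write(f"{frags.chrom[i]}\t{frags.start[i]}\t{frags.end[i]}\t"
                     f"{frags.sample_id}_{i}\t0\t{frags.strand[i]}\n")


def read_bed6(path) -> list[IntervalRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 fields")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            records.append(IntervalRecord(parts[0], int(parts[1]), int(parts[2]), name, score, strand))
    return records


def write_bed6(records: list[IntervalRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{_fmt_score(r.score)}\t{r.strand}\n")


def write_bedgraph(track: dict[str, np.ndarray], bin_width: int, path, keep_zero: bool = False) -> None:
    """Write uniformly binned values as bedGraph, run-length merging equal bins.

    ``track`` maps chrom -> per-bin values. Zero-valued runs are dropped by
    default; pass ``keep_zero=True`` to emit them for the covered region.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    with open(path, "w") as fh:
        for chrom, values in track.items():
            values = np.asarray(values, dtype=float)
            if values.size == 0:
                continue
            if not np.isfinite(values).all():
                raise ValueError(f"non-finite value in track for {chrom}")
            # run-length encode adjacent equal bins
            change = np.flatnonzero(np.diff(values)) + 1
            run_starts = np.concatenate(([0], change))
            run_ends = np.concatenate((change, [values.size]))
            for rs, re in zip(run_starts, run_ends):
                v = values[rs]
                if v == 0 and not keep_zero:
                    continue
                fh.write(f"{chrom}\t{rs * bin_width}\t{re * bin_width}\t{_fmt_score(v)}\n")


def read_bedgraph(path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a bedGraph into per-chrom (starts, ends, values) sorted arrays."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields")
            per_chrom.setdefault(parts[0], []).append((int(parts[1]), int(parts[2]), float(parts[3])))
    out = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], np.int64)
        ends = np.array([r[1] for r in rows], np.int64)
        values = np.array([r[2] for r in rows], float)
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
        out[chrom] = (starts, ends, values)
    return out


def apply_blacklist(frags: FragmentSet, blacklist: list[IntervalRecord]) -> FragmentSet:
    """Drop fragments overlapping any blacklist interval by >=1 bp."""
    if not blacklist or len(frags) == 0:
        return frags
    keep = np.ones(len(frags), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in blacklist:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        # merge so searchsorted intervals are disjoint
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        bs = np.array([m[0] for m in merged], np.int64)
        be = np.array([m[1] for m in merged], np.int64)
        m = frags.chrom == chrom
        idx = np.flatnonzero(m)
        # fragment [s,e) overlaps some blacklist interval iff the first
        # interval with end > s has start < e
        pos = np.searchsorted(be, frags.start[idx], side="right")
        hit = (pos < len(bs)) & (bs[np.minimum(pos, len(bs) - 1)] < frags.end[idx])
        keep[idx[hit]] = False
    return frags.subset(keep)
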