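"""Genomic-interval data model, BED I/O, and peak-set algebra.

All coordinates are 0-based half-open (BED convention). Overlap is
defined per-base: two intervals overlap iff they share at least one
base, i.e. ``max(starts) < min(ends)``. Strand is carried through I/O
but ignored by the overlap math.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple
import warnings

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "read_bed",
    "write_bed",
    "overlaps_any",
    "subtract",
    "consensus_peaks",
    "peak_center",
    "annotate_context",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def peak_center(interval: GenomicInterval) -> int:
    """Center coordinate, floor of the midpoint on odd spans."""
    return (interval.start + interval.end) // 2


class PeakSet:
    """An ordered, sorted collection of intervals with sample metadata."""

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        sample_id: str = "",
        condition: str = "",
    ):
        self.sample_id = sample_id
        self.condition = condition
        self.intervals: List[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PeakSet)
            and self.intervals == other.intervals
            and self.sample_id == other.sample_id
            and self.condition == other.condition
        )

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def merged(self) -> "PeakSet":
        """Union of this set's intervals as maximal non-overlapping blocks."""
        merged: List[GenomicInterval] = []
        for chrom, ivs in sorted(self.by_chrom().items()):
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                # abutting intervals merge: their per-base union is contiguous
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    merged.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
        return PeakSet(merged, sample_id=self.sample_id, condition=self.condition)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(
    path: str | os.PathLike, sample_id: str = "", condition: str = ""
) -> PeakSet:
    """Parse a BED3+ file; raises ValueError naming the offending line."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from exc
            strand = fields[5] if len(fields) > 5 else None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(intervals, sample_id=sample_id, condition=condition)


def write_bed(peaks: PeakSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Algebra
# ---------------------------------------------------------------------------

def overlaps_any(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> np.ndarray:
    """Boolean vector over ``a``: does any single b-interval share
    >= ``min_overlap`` bases with it?"""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    b_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in b.by_chrom().items():
        b_by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    out = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        if iv.chrom not in b_by_chrom:
            continue
        bs, be = b_by_chrom[iv.chrom]
        ov = np.minimum(be, iv.end) - np.maximum(bs, iv.start)
        out[i] = bool((ov >= min_overlap).any())
    return out


def subtract(a: PeakSet, b: PeakSet) -> PeakSet:
    """Per-base set difference a \\ b; intervals may split."""
    b_merged = b.merged().by_chrom()
    out: List[GenomicInterval] = []
    for iv in a:
        blocks = b_merged.get(iv.chrom, [])
        cursor = iv.start
        for blk in blocks:
            if blk.end <= cursor or blk.start >= iv.end:
                continue
            if blk.start > cursor:
                out.append(replace(iv, start=cursor, end=blk.start))
            cursor = max(cursor, blk.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(replace(iv, start=cursor))
    return PeakSet(out, sample_id=a.sample_id, condition=a.condition)


def consensus_peaks(sets: Sequence[PeakSet], min_support: int = 2) -> PeakSet:
    """Merge the union of all sets into maximal blocks; keep blocks that
    intervals from >= ``min_support`` distinct input sets overlap.

    Overlapping intervals within one input set are merged first and count
    as a single source of support.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(sets) < min_support:
        raise ValueError(
            f"min_support={min_support} exceeds number of sets ({len(sets)})"
        )
    merged_sets = [s.merged() for s in sets]
    union = PeakSet(
        [iv for s in merged_sets for iv in s], sample_id="union"
    ).merged()
    kept: List[GenomicInterval] = []
    for blk in union:
        support = 0
        for s in merged_sets:
            for iv in s.by_chrom().get(blk.chrom, []):
                if iv.overlap_length(blk) >= 1:
                    support += 1
                    break
        if support >= min_support:
            kept.append(replace(blk, score=float(support)))
    return PeakSet(kept, sample_id="consensus")


# ---------------------------------------------------------------------------
# Gene model + peak context
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene body for {self.name}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon [{s},{e}) outside gene body of {self.name}")

    @property
    def tss(self) -> int:
        return self.start if self.strand != "-" else self.end - 1


class GeneModel:
    """Minimal gene annotation: TSS, exons, gene bodies."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: List[Gene] = sorted(genes, key=lambda g: (g.chrom, g.start))

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_gff3(cls, path: str | os.PathLike) -> "GeneModel":
        """Read a minimal GFF3 subset (gene/exon features, ID/Parent tags).

        GFF3 is 1-based inclusive; converted to 0-based half-open here.
        """
        genes: Dict[str, Gene] = {}
        pending_exons: List[Tuple[str, int, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ValueError(f"{path}: line {lineno}: not GFF3")
                chrom, _, ftype, start1, end1, _, strand, _, attrs = fields[:9]
                start, end = int(start1) - 1, int(end1)
                tags = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                if ftype == "gene":
                    gid = tags.get("ID") or tags.get("gene_id") or f"gene{lineno}"
                    genes[gid] = Gene(gid, chrom, start, end, strand)
                elif ftype == "exon":
                    parent = tags.get("Parent", "")
                    pending_exons.append((parent, start, end))
        for parent, s, e in pending_exons:
            if parent in genes:
                genes[parent].exons.append((s, e))
        return cls(genes.values())


def annotate_context(
    peaks: PeakSet, genes: GeneModel, promoter_halfwidth: int = 2000
) -> List[str]:
    """Classify each peak center: promoter > exon > intron > intergenic."""
    if len(genes) == 0:
        warnings.warn("empty gene model: all peaks annotated intergenic")
        return ["intergenic"] * len(peaks)
    by_chrom: Dict[str, List[Gene]] = {}
    for g in genes.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: List[str] = []
    for iv in peaks:
        center = peak_center(iv)
        category = "intergenic"
        in_exon = in_body = near_tss = False
        for g in by_chrom.get(iv.chrom, []):
            if abs(center - g.tss) <= promoter_halfwidth:
                near_tss = True
                break
            if g.start <= center < g.end:
                in_body = True
                if any(s <= center < e for s, e in g.exons):
                    in_exon = True
        if near_tss:
            category = "promoter"
        elif in_exon:
            category = "exon"
        elif in_body:
            category = "intron"
        out.append(category)
    return out
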