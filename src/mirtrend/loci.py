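"""Expressed-locus assembly from aligned small-RNA reads.

Reads are genomic intervals (0-based, half-open, BED convention). Overlapping
reads are clustered into maximal merged loci; each locus carries its read
count and mean per-base coverage (sum of read lengths / locus length). Loci
are then restricted to an annotated miRNA interval set before entering the
screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadInterval:
    """One aligned read span. ``strand`` is '+', '-' or None (unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"empty chrom in {self!r}")
        if self.end <= self.start:
            raise ValidationError(f"end must exceed start: {self!r}")
        if self.strand not in ("+", "-", None):
            raise ValidationError(f"bad strand {self.strand!r} in {self!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Locus:
    """A merged cluster of overlapping reads."""

    chrom: str
    start: int
    end: int
    strand: str | None
    read_count: int
    coverage: float
    annotation_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def compute_locus_coverage(locus_start: int, locus_end: int,
                           member_reads: Sequence[ReadInterval]) -> float:
    """Mean per-base depth: sum of member read lengths over the locus length."""
    length = locus_end - locus_start
    if length <= 0:
        raise ValidationError("zero-length locus")
    for r in member_reads:
        if r.start < locus_start or r.end > locus_end:
            raise ValidationError(f"read {r!r} outside locus [{locus_start},{locus_end})")
    return sum(r.length for r in member_reads) / length


def assemble_loci(reads: Iterable[ReadInterval], stranded: bool = False,
                  merge_distance: int = 0) -> list[Locus]:
    """Cluster reads into maximal merged loci.

    Two reads join the same locus iff they are connected by a chain of read
    pairs whose gap (next.start - prev.end) is <= ``merge_distance``, on the
    same chromosome (and same strand when ``stranded``). The default 0 merges
    overlapping and book-ended reads, like ``bedtools merge``. The sum of the
    returned read counts equals the number of input reads.
    """
    if merge_distance < 0:
        raise ValidationError("merge_distance must be >= 0")
    reads = list(reads)
    loci: list[Locus] = []

    def key(r: ReadInterval):
        return (r.chrom, (r.strand or "") if stranded else "", r.start, r.end)

    group_strand = lambda r: r.strand if stranded else None
    current: list[ReadInterval] = []

    def flush() -> None:
        if not current:
            return
        start = current[0].start
        end = max(r.end for r in current)
        loci.append(Locus(
            chrom=current[0].chrom,
            start=start,
            end=end,
            strand=group_strand(current[0]),
            read_count=len(current),
            coverage=compute_locus_coverage(start, end, current),
        ))

    prev = None
    cur_end = None
    for r in sorted(reads, key=key):
        same_group = (
            prev is not None
            and r.chrom == prev.chrom
            and (not stranded or r.strand == prev.strand)
        )
        if same_group and r.start - cur_end <= merge_distance:
            current.append(r)
            cur_end = max(cur_end, r.end)
        else:
            flush()
            current = [r]
            cur_end = r.end
        prev = r
    flush()
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.strand or ""))
    return loci


def annotate_loci(loci: Sequence[Locus],
                  annotation: Sequence[tuple[str, int, int, str]]) -> list[Locus]:
    """Assign annotation IDs to loci and drop unannotated loci.

    ``annotation`` is a sequence of (chrom, start, end, id) intervals. A locus
    overlapping (any shared base) exactly one annotation takes its ID; a locus
    overlapping several is assigned to the one with the largest overlap, ties
    broken by (chrom, start, end, id) sort order with a logged warning; a
    locus overlapping none is dropped.
    """
    trees: dict[str, IntervalTree] = {}
    for rank, (chrom, start, end, ann_id) in enumerate(
            sorted(annotation, key=lambda a: (a[0], a[1], a[2], a[3]))):
        if end <= start:
            raise ValidationError(f"bad annotation interval {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end, (rank, ann_id))

    out: list[Locus] = []
    for locus in loci:
        tree = trees.get(locus.chrom)
        hits = tree.overlap(locus.start, locus.end) if tree is not None else set()
        if not hits:
            continue
        scored = sorted(
            hits,
            key=lambda iv: (-(min(locus.end, iv.end) - max(locus.start, iv.begin)),
                            iv.data[0]),
        )
        if len(scored) > 1:
            best_ovl = min(locus.end, scored[0].end) - max(locus.start, scored[0].begin)
            second_ovl = min(locus.end, scored[1].end) - max(locus.start, scored[1].begin)
            if best_ovl == second_ovl:
                log.warning(
                    "locus %s:%d-%d overlaps multiple annotations equally; "
                    "assigned %s by sort order",
                    locus.chrom, locus.start, locus.end, scored[0].data[1],
                )
        out.append(Locus(
            chrom=locus.chrom, start=locus.start, end=locus.end,
            strand=locus.strand, read_count=locus.read_count,
            coverage=locus.coverage, annotation_id=scored[0].data[1],
        ))
    return out
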