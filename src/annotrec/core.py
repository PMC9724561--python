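"""Domain model for genomic annotations.

Intervals, transcripts, genes and indexed annotation sets, plus
spliced-sequence extraction.  All coordinates are 0-based half-open
on the internal side; conversion from the 1-based inclusive GTF
convention happens once, at the I/O boundary (:mod:`annotrec.io`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

log = logging.getLogger("annotrec")

VALID_STRANDS = frozenset({"+", "-", "."})


class AnnotationError(ValueError):
    """Invalid annotation structure (unsorted/overlapping exons, bad strand...)."""


class CoordinateError(AnnotationError):
    """A coordinate falls outside the sequence it refers to."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).  Ordering is
    (chrom, start, end, strand), which gives the deterministic sort used
    throughout the package.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def strictly_contains(self, other: "GenomicInterval") -> bool:
        return self.contains(other) and (self.start, self.end) != (
            other.start,
            other.end,
        )

    def gap(self, other: "GenomicInterval") -> int:
        """bp gap between the closest span ends; 0 when overlapping or
        touching; -1 when the intervals sit on different chromosomes."""
        if self.chrom != other.chrom:
            return -1
        return max(0, max(self.start, other.start) - min(self.end, other.end))


def merge_intervals(
    intervals: Sequence[GenomicInterval], *, warn_context: str | None = None
) -> tuple[GenomicInterval, ...]:
    """Sort intervals and merge any that overlap or abut.

    Real assembler GTFs occasionally emit touching exon records; they are
    merged with a warning rather than rejected.
    """
    if not intervals:
        return ()
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = [ordered[0]]
    collapsed = False
    for iv in ordered[1:]:
        prev = merged[-1]
        if iv.start <= prev.end:  # overlap or abut
            collapsed = True
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end), prev.strand
            )
        else:
            merged.append(iv)
    if collapsed and warn_context:
        log.warning("merged overlapping/abutting exons in %s", warn_context)
    return tuple(merged)


def derive_introns(exons: Sequence[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Gaps between consecutive exons, in genomic order.

    Empty for a single-exon chain.  Exons must already be sorted,
    non-overlapping and non-adjacent (the :class:`Transcript` invariant);
    anything else raises :class:`AnnotationError`.
    """
    for prev, nxt in zip(exons, exons[1:]):
        if prev.chrom != nxt.chrom or prev.strand != nxt.strand:
            raise AnnotationError("exons span multiple chromosomes/strands")
        if nxt.start <= prev.end:
            raise AnnotationError(f"exons not sorted/disjoint: {prev} then {nxt}")
    return tuple(
        GenomicInterval(prev.chrom, prev.end, nxt.start, prev.strand)
        for prev, nxt in zip(exons, exons[1:])
    )


@dataclass(frozen=True)
class Transcript:
    """An exon chain on one strand of one chromosome.

    Exons are normalised at construction: sorted ascending and merged when
    they overlap or abut, so every stored chain satisfies the invariants
    the rest of the package relies on (introns = gaps between consecutive
    exons, span = first start to last end).
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} mixes chromosomes or strands"
            )
        object.__setattr__(
            self,
            "exons",
            merge_intervals(self.exons, warn_context=self.transcript_id),
        )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @cached_property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @cached_property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return derive_introns(self.exons)

    @cached_property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (start, end) intron coordinates; the chain-match key."""
        return tuple((i.start, i.end) for i in self.introns)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1


@dataclass
class Gene:
    """A named locus grouping one or more transcripts on one chromosome."""

    gene_id: str
    symbol: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        if len({t.chrom for t in self.transcripts}) != 1:
            raise AnnotationError(f"gene {self.gene_id} spans chromosomes")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        strands = {t.strand for t in self.transcripts}
        return strands.pop() if len(strands) == 1 else "."

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.interval.start for t in self.transcripts),
            max(t.interval.end for t in self.transcripts),
            self.strand,
        )

    def exonic_overlap_bp(self, t: Transcript) -> int:
        """Total bp of exon-exon overlap between ``t`` and this gene's
        merged exonic footprint."""
        footprint = merge_intervals(
            [e for tr in self.transcripts for e in tr.exons]
        )
        total = 0
        for e in t.exons:
            for f in footprint:
                total += e.overlap_bp(f)
        return total


class AnnotationSet:
    """A collection of genes with a per-chromosome interval index.

    The index answers span-overlap queries; strand filtering is applied on
    top of the positional hit list.  Transcripts with strand ``.`` are
    returned by unstranded queries only.
    """

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._by_tid: dict[str, Transcript] = {}
        self._gene_of: dict[str, str] = {}
        for g in self.genes.values():
            for t in g.transcripts:
                if t.transcript_id in self._by_tid:
                    raise AnnotationError(
                        f"transcript {t.transcript_id} under two genes"
                    )
                self._by_tid[t.transcript_id] = t
                self._gene_of[t.transcript_id] = g.gene_id
        self._index: dict[str, IntervalTree] | None = None

    @classmethod
    def from_transcripts(
        cls,
        transcripts: Iterable[Transcript],
        symbols: Mapping[str, str] | None = None,
    ) -> "AnnotationSet":
        by_gene: dict[str, list[Transcript]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        symbols = symbols or {}
        return cls(
            Gene(gid, symbols.get(gid, gid), ts) for gid, ts in by_gene.items()
        )

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return len(self._by_tid)

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes.values():
            yield from g.transcripts

    def transcript(self, transcript_id: str) -> Transcript:
        return self._by_tid[transcript_id]

    def gene_of(self, transcript_id: str) -> Gene:
        return self.genes[self._gene_of[transcript_id]]

    # -- overlap index ----------------------------------------------------
    def _build_index(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for t in self.transcripts():
            trees.setdefault(t.chrom, IntervalTree()).addi(
                t.interval.start, t.interval.end, t
            )
        return trees

    def overlap_query(
        self, query: GenomicInterval, same_strand: bool = False
    ) -> list[Transcript]:
        """Transcripts whose span overlaps ``query`` by >= 1 bp.

        With ``same_strand`` the query strand must match the transcript
        strand exactly; ``.`` transcripts then never match.  Results are
        ordered by (chrom, start, transcript_id).
        """
        if self._index is None:
            self._index = self._build_index()
        tree = self._index.get(query.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(query.start, query.end)]
        if same_strand:
            hits = [t for t in hits if t.strand == query.strand and t.strand != "."]
        hits.sort(key=lambda t: (t.chrom, t.interval.start, t.transcript_id))
        return hits


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def spliced_sequence(transcript: Transcript, genome: Mapping[str, str]) -> str:
    """Concatenated exon sequence of ``transcript``, uppercase.

    Exons are concatenated in genomic order and the whole product is
    reverse-complemented when the transcript is on the ``-`` strand,
    matching what gffread emits for a stranded GTF record.
    """
    chrom = transcript.chrom
    if chrom not in genome:
        raise CoordinateError(f"chromosome {chrom!r} absent from genome")
    seq = genome[chrom]
    if transcript.interval.end > len(seq):
        raise CoordinateError(
            f"transcript {transcript.transcript_id} extends to "
            f"{transcript.interval.end} on {chrom} of length {len(seq)}"
        )
    parts = [seq[e.start : e.end] for e in transcript.exons]
    out = "".join(parts).upper()
    if transcript.strand == "-":
        out = str(Seq(out).reverse_complement())
    return out
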