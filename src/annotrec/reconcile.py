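"""Reconcile an assembled transcriptome with a reference annotation.

Each assembled transcript is matched against the reference and assigned
either a known gene (labelled by its reference symbol) or kept as a novel
locus under its assembler gene id (``STRG`` prefix).  The five match
classes mirror the gffcompare class codes ``=``, ``j``, ``i``, ``x`` and
``u``:

exact
    multi-exon transcript whose ordered intron chain equals a reference
    transcript's chain, or a single-exon transcript with >= 80% reciprocal
    span overlap with a single-exon reference transcript on the same strand
isoform
    >= 1 bp same-strand exon-exon overlap with a reference gene; assigned
    to the gene with the greatest exonic overlap
novel_intronic
    span fully inside a reference intron, same strand, no exonic overlap
novel_antisense
    exonic overlap only with opposite-strand reference exons
novel_intergenic
    none of the above
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .core import AnnotationSet, GenomicInterval, Transcript

log = logging.getLogger("annotrec")

SINGLE_EXON_RECIPROCAL_OVERLAP = 0.8


class MatchClass(str, Enum):
    EXACT = "exact"
    ISOFORM = "isoform"
    NOVEL_INTRONIC = "novel_intronic"
    NOVEL_ANTISENSE = "novel_antisense"
    NOVEL_INTERGENIC = "novel_intergenic"

    @property
    def is_known(self) -> bool:
        return self in (MatchClass.EXACT, MatchClass.ISOFORM)


@dataclass(frozen=True)
class ReconciledRecord:
    transcript_id: str
    assigned_gene: str  # reference symbol (known) or assembler gene id (novel)
    match_class: MatchClass
    ref_transcript_id: str = ""  # populated for exact matches only
    overlap_bp: int = 0  # exonic overlap with the assigned reference gene


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def match_transcript(
    t: Transcript,
    ref: AnnotationSet,
    single_exon_overlap: float = SINGLE_EXON_RECIPROCAL_OVERLAP,
) -> ReconciledRecord:
    """Classify one assembled transcript against the reference.

    Rules are applied in order (exact, isoform, novel_intronic,
    novel_antisense, novel_intergenic); the first that fires wins.
    """
    return _match(t, ref, single_exon_overlap)[0]


def _match(
    t: Transcript, ref: AnnotationSet, single_exon_overlap: float
) -> tuple[ReconciledRecord, str | None]:
    """Classification plus the matched reference gene_id (None when novel)."""
    candidates = ref.overlap_query(t.interval, same_strand=False)
    same = [c for c in candidates if c.strand == t.strand and t.strand != "."]

    # (1) exact: identical intron chain / single-exon reciprocal overlap
    exact_hit = None
    if t.is_multi_exon:
        for c in same:
            if c.is_multi_exon and c.intron_chain == t.intron_chain:
                exact_hit = c
                break
    else:
        best_ro = 0.0
        for c in same:
            if not c.is_multi_exon:
                ro = _reciprocal_overlap(t.interval, c.interval)
                if ro >= single_exon_overlap and ro > best_ro:
                    exact_hit, best_ro = c, ro
    if exact_hit is not None:
        gene = ref.gene_of(exact_hit.transcript_id)
        return (
            ReconciledRecord(
                t.transcript_id,
                gene.symbol,
                MatchClass.EXACT,
                ref_transcript_id=exact_hit.transcript_id,
                overlap_bp=gene.exonic_overlap_bp(t),
            ),
            gene.gene_id,
        )

    # (2) isoform: best same-strand exonic overlap with a reference gene
    by_gene: dict[str, int] = {}
    for c in same:
        gid = ref.gene_of(c.transcript_id).gene_id
        if gid not in by_gene:
            by_gene[gid] = ref.genes[gid].exonic_overlap_bp(t)
    exonic = {gid: bp for gid, bp in by_gene.items() if bp > 0}
    if exonic:
        best_gid = min(exonic, key=lambda gid: (-exonic[gid], gid))
        return (
            ReconciledRecord(
                t.transcript_id,
                ref.genes[best_gid].symbol,
                MatchClass.ISOFORM,
                overlap_bp=exonic[best_gid],
            ),
            best_gid,
        )

    # (3) novel_intronic: fully inside a same-strand reference intron
    for c in same:
        for intron in c.introns:
            if intron.contains(t.interval):
                return (
                    ReconciledRecord(
                        t.transcript_id, t.gene_id, MatchClass.NOVEL_INTRONIC
                    ),
                    None,
                )

    # (4) novel_antisense: exonic overlap with opposite-strand exons only
    for c in candidates:
        if c.strand == t.strand or c.strand == "." or t.strand == ".":
            continue
        if any(e.overlap_bp(ce) > 0 for e in t.exons for ce in c.exons):
            return (
                ReconciledRecord(
                    t.transcript_id, t.gene_id, MatchClass.NOVEL_ANTISENSE
                ),
                None,
            )

    # (5) otherwise intergenic (or intronic/antisense overlap too weak)
    return (
        ReconciledRecord(t.transcript_id, t.gene_id, MatchClass.NOVEL_INTERGENIC),
        None,
    )


def reconcile_annotation(
    assembly: AnnotationSet,
    ref: AnnotationSet,
    single_exon_overlap: float = SINGLE_EXON_RECIPROCAL_OVERLAP,
) -> tuple[AnnotationSet, list[ReconciledRecord]]:
    """Reconcile every assembled transcript with the reference.

    Returns the reconciled annotation (known transcripts grouped under
    their reference gene, novel transcripts under their assembler gene id)
    and one record per input transcript.  Conservation holds by
    construction: every assembled transcript appears exactly once.
    """
    records: list[ReconciledRecord] = []
    regrouped: list[Transcript] = []
    symbols: dict[str, str] = {}
    for t in assembly.transcripts():
        rec, ref_gid = _match(t, ref, single_exon_overlap)
        records.append(rec)
        if rec.match_class.is_known:
            new_gid = ref_gid  # group under the reference gene
            symbols[new_gid] = ref.genes[ref_gid].symbol
        else:
            new_gid = t.gene_id
            symbols.setdefault(new_gid, new_gid)
        regrouped.append(Transcript(t.transcript_id, new_gid, t.exons))
    out = AnnotationSet.from_transcripts(regrouped, symbols)
    n_known = sum(1 for r in records if r.match_class.is_known)
    log.info(
        "reconciled %d transcripts: %d known, %d novel",
        len(records), n_known, len(records) - n_known,
    )
    return out, records


def records_table(records: Iterable[ReconciledRecord]) -> str:
    """TSV rendering of reconciliation records."""
    lines = ["transcript_id\tassigned_gene\tmatch_class\tref_transcript_id\toverlap_bp"]
    for r in records:
        lines.append(
            f"{r.transcript_id}\t{r.assigned_gene}\t{r.match_class.value}\t"
            f"{r.ref_transcript_id}\t{r.overlap_bp}"
        )
    return "\n".join(lines) + "\n"
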