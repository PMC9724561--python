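"""Positional classification of lncRNAs against coding genes.

Each lncRNA is paired with a partner coding gene (the overlapping gene
with the largest exonic overlap, else the nearest gene within a window)
and described by its geometry relative to that partner:

* relation ``genic`` (spans overlap) or ``intergenic`` (no overlap within
  the window); ``orphan`` when no coding gene lies within the window.
* direction ``sense``/``antisense`` by strand equality with the partner.
* location: genic lncRNAs are ``exonic`` (>= 1 bp exon-exon overlap),
  ``containing`` (lncRNA span strictly contains the partner span) or
  ``intronic``; intergenic ones are ``upstream``/``downstream`` relative
  to the partner's orientation.
* subtype (intergenic only): ``divergent`` = antisense and upstream of
  the partner (head-to-head), ``convergent`` = antisense and downstream
  (tail-to-tail), ``same_strand`` = sense.

Distance is the bp gap between the closest span ends (0 for genic).
The default window is 100 kb.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .core import AnnotationSet, Transcript

log = logging.getLogger("annotrec")

DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class LncRNAClass:
    transcript_id: str
    partner_gene: str | None
    relation: str  # genic | intergenic | orphan
    direction: str | None = None  # sense | antisense
    location: str | None = None  # exonic|intronic|containing / upstream|downstream
    subtype: str | None = None  # divergent | convergent | same_strand (intergenic)
    distance: int = 0


def classify_lncrna(
    lnc: Transcript, annotation: AnnotationSet, max_window: int = DEFAULT_WINDOW
) -> LncRNAClass:
    """Classify one lncRNA against an annotation of coding genes.

    ``annotation`` must contain coding genes only (filter upstream).
    """
    if max_window <= 0:
        raise ValueError("max_window must be positive")
    span = lnc.interval

    # partner: overlapping gene with largest exonic overlap, else nearest
    overlapping: dict[str, int] = {}
    for t in annotation.overlap_query(span, same_strand=False):
        gid = annotation.gene_of(t.transcript_id).gene_id
        if gid not in overlapping:
            overlapping[gid] = annotation.genes[gid].exonic_overlap_bp(lnc)
    if overlapping:
        gid = min(overlapping, key=lambda g: (-overlapping[g], g))
        return _genic(lnc, annotation.genes[gid])

    nearest: tuple[int, str] | None = None
    for gid, gene in annotation.genes.items():
        if gene.chrom != span.chrom:
            continue
        gap = gene.span.gap(span)
        if gap > max_window:
            continue
        if nearest is None or (gap, gid) < nearest:
            nearest = (gap, gid)
    if nearest is None:
        return LncRNAClass(lnc.transcript_id, None, "orphan")
    return _intergenic(lnc, annotation.genes[nearest[1]], nearest[0])


def _direction(lnc: Transcript, partner) -> str:
    return "sense" if lnc.strand == partner.strand else "antisense"


def _genic(lnc: Transcript, partner) -> LncRNAClass:
    exonic = partner.exonic_overlap_bp(lnc) > 0
    if exonic:
        location = "exonic"
    elif lnc.interval.strictly_contains(partner.span):
        location = "containing"
    else:
        location = "intronic"
    return LncRNAClass(
        lnc.transcript_id,
        partner.symbol,
        "genic",
        direction=_direction(lnc, partner),
        location=location,
        distance=0,
    )


def _intergenic(lnc: Transcript, partner, gap: int) -> LncRNAClass:
    before = lnc.interval.end <= partner.span.start
    # upstream/downstream in the partner's frame of reference
    if partner.strand == "-":
        location = "downstream" if before else "upstream"
    else:
        location = "upstream" if before else "downstream"
    direction = _direction(lnc, partner)
    if direction == "sense":
        subtype = "same_strand"
    elif location == "upstream":
        subtype = "divergent"
    else:
        subtype = "convergent"
    return LncRNAClass(
        lnc.transcript_id,
        partner.symbol,
        "intergenic",
        direction=direction,
        location=location,
        subtype=subtype,
        distance=gap,
    )


def classify_all(
    lncs: Iterable[Transcript],
    annotation: AnnotationSet,
    max_window: int = DEFAULT_WINDOW,
) -> list[LncRNAClass]:
    out = [classify_lncrna(t, annotation, max_window) for t in lncs]
    log.info("classified %d lncRNAs", len(out))
    return out


def lncrna_table(classes: Iterable[LncRNAClass]) -> str:
    lines = ["transcript_id\tpartner_gene\trelation\tdirection\tlocation\tsubtype\tdistance"]
    for c in classes:
        lines.append(
            "\t".join(
                str(x) if x is not None else ""
                for x in (
                    c.transcript_id, c.partner_gene, c.relation,
                    c.direction, c.location, c.subtype, c.distance,
                )
            )
        )
    return "\n".join(lines) + "\n"
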