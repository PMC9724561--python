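"""Paralog / homolog / missing-gene-isoform calls for novel proteins.

Inputs are tabular protein-homology hits (one best hit per query is
selected by evalue, then bitscore), the genomic locus of each query's
transcript and of each subject's annotated gene.  Hits in the configured
identity band (default 90-100%) are classified:

* the query locus overlaps the subject locus -> ``missing_gene_isoform``
  (the novel transcript is an isoform of a gene dropped from the current
  annotation);
* same chromosome and the gap between loci is below the window (default
  0.5 Mb) -> ``paralog``;
* otherwise (different chromosome, distant locus, or subject unplaced)
  -> ``homolog_missing_gene``.

"Within the same locus" is operationalised as gap-between-spans below
the window on one chromosome, excluding overlap (overlap routes to the
isoform call).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomicInterval
from .io import BlastHit

log = logging.getLogger("annotrec")


@dataclass(frozen=True)
class HomologyParams:
    min_identity: float = 90.0
    max_identity: float = 100.0
    locus_window: int = 500_000
    evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity <= self.max_identity <= 100):
            raise ValueError("require 0 <= min_identity <= max_identity <= 100")
        if self.locus_window <= 0:
            raise ValueError("locus_window must be positive")


@dataclass(frozen=True)
class HomologyCall:
    query_protein: str
    subject_protein: str
    pident: float
    call: str  # paralog | homolog_missing_gene | missing_gene_isoform
    query_locus: GenomicInterval
    subject_locus: GenomicInterval | None  # None when the subject is unplaced
    gap_bp: int  # -1 when loci are on different chromosomes / unplaced


@dataclass(frozen=True)
class DroppedHit:
    query_protein: str
    subject_protein: str
    pident: float
    reason: str


def best_hit_per_query(hits: Sequence[BlastHit]) -> dict[str, BlastHit]:
    """One hit per query: lowest evalue, ties by highest bitscore, then
    first occurrence.  Deterministic for any input order of equal hits."""
    best: dict[str, tuple[float, float, int]] = {}
    out: dict[str, BlastHit] = {}
    for i, h in enumerate(hits):
        key = (h.evalue, -h.bitscore, i)
        if h.qseqid not in best or key < best[h.qseqid]:
            best[h.qseqid] = key
            out[h.qseqid] = h
    return out


def assign_homology(
    best_hits: Mapping[str, BlastHit],
    query_loci: Mapping[str, GenomicInterval],
    subject_loci: Mapping[str, GenomicInterval | None],
    params: HomologyParams = HomologyParams(),
) -> tuple[list[HomologyCall], list[DroppedHit]]:
    """Classify each best hit per the identity band and locus-distance rule.

    ``subject_loci`` may map a subject to ``None`` (unplaced contig /
    absent from the annotation); such hits become ``homolog_missing_gene``.
    A query without a locus is a pipeline wiring bug and raises.
    """
    calls: list[HomologyCall] = []
    dropped: list[DroppedHit] = []
    for qid in sorted(best_hits):
        h = best_hits[qid]
        if qid not in query_loci:
            raise KeyError(f"query {qid} has no genomic locus")
        if h.evalue > params.evalue_max:
            dropped.append(DroppedHit(qid, h.sseqid, h.pident, "evalue"))
            continue
        if not (params.min_identity <= h.pident <= params.max_identity):
            dropped.append(DroppedHit(qid, h.sseqid, h.pident, "identity"))
            continue
        qloc = query_loci[qid]
        sloc = subject_loci.get(h.sseqid)
        if sloc is None:
            calls.append(
                HomologyCall(qid, h.sseqid, h.pident, "homolog_missing_gene",
                             qloc, None, -1)
            )
            continue
        gap = qloc.gap(sloc)
        if gap >= 0 and qloc.overlaps(sloc):
            call = "missing_gene_isoform"
        elif gap >= 0 and gap < params.locus_window:
            call = "paralog"
        else:
            call = "homolog_missing_gene"
        calls.append(HomologyCall(qid, h.sseqid, h.pident, call, qloc, sloc, gap))
    log.info("homology: %d calls, %d dropped", len(calls), len(dropped))
    return calls, dropped


def identity_histogram(
    hits: Iterable[BlastHit], bin_width: float = 5.0
) -> dict[str, int]:
    """Counts of best-hit identities in fixed-width percent bins
    (structure of a percent-identity distribution plot)."""
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    labels = [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(len(edges) - 1)]
    counts = dict.fromkeys(labels, 0)
    for h in hits:
        idx = min(int(h.pident // bin_width), len(labels) - 1)
        counts[labels[idx]] += 1
    return counts


def merge_orthology(
    calls: Sequence[HomologyCall], orthology: Mapping[str, tuple[str, str]]
) -> list[dict]:
    """Join eggNOG-style orthology annotations (query -> (group,
    description)) onto homology calls; a plain table-join, no execution."""
    rows = []
    for c in calls:
        group, desc = orthology.get(c.query_protein, ("", ""))
        rows.append(
            {
                "query_protein": c.query_protein,
                "subject_protein": c.subject_protein,
                "pident": c.pident,
                "call": c.call,
                "gap_bp": c.gap_bp,
                "ortholog_group": group,
                "ortholog_description": desc,
            }
        )
    return rows


def calls_table(calls: Sequence[HomologyCall], dropped: Sequence[DroppedHit]) -> str:
    lines = [
        "query_protein\tsubject_protein\tpident\tcall\tquery_locus\tsubject_locus\tgap_bp"
    ]
    for c in calls:
        qloc = f"{c.query_locus.chrom}:{c.query_locus.start}-{c.query_locus.end}"
        sloc = (
            f"{c.subject_locus.chrom}:{c.subject_locus.start}-{c.subject_locus.end}"
            if c.subject_locus is not None
            else "unplaced"
        )
        lines.append(
            f"{c.query_protein}\t{c.subject_protein}\t{c.pident}\t{c.call}\t"
            f"{qloc}\t{sloc}\t{c.gap_bp}"
        )
    for d in dropped:
        lines.append(
            f"{d.query_protein}\t{d.subject_protein}\t{d.pident}\t"
            f"dropped_{d.reason}\t\t\t"
        )
    return "\n".join(lines) + "\n"
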