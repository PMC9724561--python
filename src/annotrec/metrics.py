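"""Six-level accuracy assessment of a predicted annotation, plus ExN50.

A predicted GTF is compared against a reference (taken as truth) at the
base, exon, intron, intron-chain, transcript and locus levels, in the
style of gffcompare.  Precision is TP/(TP+FP) and recall TP/(TP+FN);
their harmonic mean (F1) summarises each level.

Matching rules per level:

base
    strand-aware exonic base arithmetic; TP = |P & R| in bp.
exon / intron
    unique exact coordinates (chrom, start, end, strand).
intron_chain
    a predicted multi-exon transcript matches when its ordered intron
    chain equals some reference chain; precision counts predicted
    multi-exon transcripts, recall counts reference multi-exon
    transcripts whose chain was produced.
transcript
    intron-chain match, or for single-exon transcripts >= 80% reciprocal
    span overlap with a single-exon mate on the same strand.
locus
    transcripts clustered by same-strand exonic overlap (transitive
    closure); a predicted locus is TP when any of its transcripts has a
    transcript-level match, a reference locus is found when any of its
    transcripts is matched.

Terminal-exon coordinates are matched exactly (no fuzzy end tolerance),
and unstranded transcripts are excluded from all levels (their count is
logged).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import AnnotationSet, GenomicInterval, Transcript
from .io import QuantRecord

log = logging.getLogger("annotrec")

LEVELS = ("base", "exon", "intron", "intron_chain", "transcript", "locus")
SINGLE_EXON_RECIPROCAL_OVERLAP = 0.8


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class LevelMetrics:
    """TP/FP/FN and derived rates at one assessment level.

    ``tp`` counts matched predicted items and ``fn`` unmatched reference
    items; at the asymmetric levels (chain, transcript, locus) recall is
    therefore computed from the reference side as (ref_total - fn) /
    ref_total, which coincides with tp/(tp+fn) at the set-based levels.
    """

    level: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # a zero denominator was reported as 0

    @classmethod
    def from_counts(
        cls, level: str, matched_pred: int, pred_total: int,
        matched_ref: int, ref_total: int,
    ) -> "LevelMetrics":
        degenerate = pred_total == 0 or ref_total == 0
        precision = matched_pred / pred_total if pred_total else 0.0
        recall = matched_ref / ref_total if ref_total else 0.0
        return cls(
            level=level,
            tp=matched_pred,
            fp=pred_total - matched_pred,
            fn=ref_total - matched_ref,
            precision=precision,
            recall=recall,
            f1=f1(precision, recall),
            degenerate=degenerate,
        )


# ---------------------------------------------------------------------------
# level computations
# ---------------------------------------------------------------------------

def _stranded(annotation: AnnotationSet) -> list[Transcript]:
    ts = [t for t in annotation.transcripts() if t.strand in "+-"]
    skipped = annotation.n_transcripts - len(ts)
    if skipped:
        log.warning("excluded %d unstranded transcripts from evaluation", skipped)
    return ts


def _merged_exon_bp(ts: Sequence[Transcript]) -> dict[tuple[str, str], list[tuple[int, int]]]:
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for t in ts:
        for e in t.exons:
            by_key.setdefault((t.chrom, t.strand), []).append((e.start, e.end))
    out = {}
    for key, ivs in by_key.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[key] = [(s, e) for s, e in merged]
    return out


def _intersect_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _base_level(pred: Sequence[Transcript], ref: Sequence[Transcript]) -> LevelMetrics:
    p = _merged_exon_bp(pred)
    r = _merged_exon_bp(ref)
    p_bp = sum(e - s for ivs in p.values() for s, e in ivs)
    r_bp = sum(e - s for ivs in r.values() for s, e in ivs)
    tp = sum(_intersect_bp(p[k], r[k]) for k in p.keys() & r.keys())
    return LevelMetrics.from_counts("base", tp, p_bp, tp, r_bp)


def _feature_sets(ts: Sequence[Transcript], what: str) -> set[tuple]:
    out = set()
    for t in ts:
        parts = t.exons if what == "exon" else t.introns
        for p in parts:
            out.add((t.chrom, p.start, p.end, t.strand))
    return out


def _set_level(level: str, p: set, r: set) -> LevelMetrics:
    tp = len(p & r)
    return LevelMetrics.from_counts(level, tp, len(p), tp, len(r))


def _chain_key(t: Transcript) -> tuple:
    return (t.chrom, t.strand, t.intron_chain)


def _single_exon_match(
    t: Transcript,
    singles: dict[tuple[str, str], list[GenomicInterval]],
    min_reciprocal: float,
) -> bool:
    for iv in singles.get((t.chrom, t.strand), []):
        ov = t.interval.overlap_bp(iv)
        if ov and min(ov / len(t.interval), ov / len(iv)) >= min_reciprocal:
            return True
    return False


def _transcript_matches(
    ts: Sequence[Transcript],
    other: Sequence[Transcript],
    min_reciprocal: float,
) -> list[bool]:
    chains = {_chain_key(t) for t in other if t.is_multi_exon}
    singles: dict[tuple[str, str], list[GenomicInterval]] = {}
    for t in other:
        if not t.is_multi_exon:
            singles.setdefault((t.chrom, t.strand), []).append(t.interval)
    flags = []
    for t in ts:
        if t.is_multi_exon:
            flags.append(_chain_key(t) in chains)
        else:
            flags.append(_single_exon_match(t, singles, min_reciprocal))
    return flags


def _cluster_loci(ts: Sequence[Transcript]) -> list[list[int]]:
    """Indices of ``ts`` grouped into loci by same-strand exonic overlap
    (transitive closure via union-find over an exon sweep)."""
    parent = list(range(len(ts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for i, t in enumerate(ts):
        for e in t.exons:
            by_key.setdefault((t.chrom, t.strand), []).append((e.start, e.end, i))
    for exons in by_key.values():
        exons.sort()
        active: list[tuple[int, int]] = []  # (end, idx) not yet expired
        for s, e, i in exons:
            active = [(end, j) for end, j in active if end > s]
            for _, j in active:
                union(i, j)
            active.append((e, i))
    groups: dict[int, list[int]] = {}
    for i in range(len(ts)):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def evaluate(
    pred: AnnotationSet,
    ref: AnnotationSet,
    single_exon_overlap: float = SINGLE_EXON_RECIPROCAL_OVERLAP,
) -> list[LevelMetrics]:
    """Compare a predicted annotation against a reference at all six levels.

    Returns one :class:`LevelMetrics` per level, in the canonical order
    ``base, exon, intron, intron_chain, transcript, locus``.  Empty
    inputs yield zero precision/recall flagged as degenerate.
    """
    p = _stranded(pred)
    r = _stranded(ref)

    out = [_base_level(p, r)]
    for level in ("exon", "intron"):
        out.append(_set_level(level, _feature_sets(p, level), _feature_sets(r, level)))

    p_multi = [t for t in p if t.is_multi_exon]
    r_multi = [t for t in r if t.is_multi_exon]
    r_chains = {_chain_key(t) for t in r_multi}
    p_chains = {_chain_key(t) for t in p_multi}
    out.append(
        LevelMetrics.from_counts(
            "intron_chain",
            sum(_chain_key(t) in r_chains for t in p_multi),
            len(p_multi),
            sum(_chain_key(t) in p_chains for t in r_multi),
            len(r_multi),
        )
    )

    p_flags = _transcript_matches(p, r, single_exon_overlap)
    r_flags = _transcript_matches(r, p, single_exon_overlap)
    out.append(
        LevelMetrics.from_counts(
            "transcript", sum(p_flags), len(p), sum(r_flags), len(r)
        )
    )

    p_loci = _cluster_loci(p)
    r_loci = _cluster_loci(r)
    out.append(
        LevelMetrics.from_counts(
            "locus",
            sum(any(p_flags[i] for i in locus) for locus in p_loci),
            len(p_loci),
            sum(any(r_flags[i] for i in locus) for locus in r_loci),
            len(r_loci),
        )
    )
    return out


def metrics_table(metrics: Iterable[LevelMetrics]) -> str:
    lines = ["level\ttp\tfp\tfn\tprecision\trecall\tf1"]
    for m in metrics:
        lines.append(
            f"{m.level}\t{m.tp}\t{m.fp}\t{m.fn}\t"
            f"{m.precision:.6f}\t{m.recall:.6f}\t{m.f1:.6f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# ExN50
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExN50Result:
    fraction: float
    n_transcripts: int
    exn50: int


def exn50(records: Sequence[QuantRecord], fraction: float = 0.9) -> ExN50Result:
    """Expression-weighted N50.

    Transcripts are ranked by TPM descending (ties: longer first, then
    id); the minimal prefix whose cumulative TPM reaches ``fraction`` of
    the total defines the expression-dominant set, and the result is the
    N50 of that set's lengths: the largest L such that transcripts of
    length >= L cover at least half of the set's total length.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    total = sum(r.tpm for r in records)
    if total <= 0:
        raise ValueError("all TPM values are zero")
    ranked = sorted(records, key=lambda r: (-r.tpm, -r.length, r.transcript_id))
    cum = 0.0
    prefix: list[QuantRecord] = []
    target = fraction * total
    for rec in ranked:
        prefix.append(rec)
        cum += rec.tpm
        if cum >= target or abs(cum - target) < 1e-9:
            break
    lengths = sorted((r.length for r in prefix), reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return ExN50Result(fraction, len(prefix), L)
    raise AssertionError("unreachable")
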