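"""Shared fixtures, small annotation builders and brute-force oracles.

The oracles here are deliberately naive, independent re-implementations
(per-base sets, all-pairs scans, exhaustive enumeration) used to check
the package's optimised code paths on randomised inputs.
"""
from __future__ import annotations

import random

import pytest

from annotrec.core import AnnotationSet, GenomicInterval, Transcript
from annotrec.simulate import FixtureSpec, generate


def tx(tid, gid, chrom, strand, *exons) -> Transcript:
    """Shorthand transcript builder from (start, end) pairs."""
    return Transcript(
        tid, gid, tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    )


def random_annotation(
    rng: random.Random,
    n_genes: int = 12,
    region: int = 100_000,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
) -> AnnotationSet:
    """Random transcripts (possibly overlapping) for oracle comparisons."""
    transcripts = []
    for g in range(n_genes):
        chrom = rng.choice(chroms)
        strand = rng.choice("+-")
        for t_i in range(rng.randint(1, 3)):
            n_exons = rng.randint(1, 5)
            pos = rng.randint(0, region)
            exons = []
            for _ in range(n_exons):
                length = rng.randint(50, 400)
                exons.append((pos, pos + length))
                pos += length + rng.randint(30, 800)
            transcripts.append(tx(f"t{g}.{t_i}", f"g{g}", chrom, strand, *exons))
    return AnnotationSet.from_transcripts(transcripts)


def perturbed_copy(rng: random.Random, annotation: AnnotationSet) -> AnnotationSet:
    """Drop, shift and add transcripts to make a 'predicted' set."""
    out = []
    for t in annotation.transcripts():
        r = rng.random()
        if r < 0.2:
            continue  # dropped
        if r < 0.45 and t.is_multi_exon:
            exons = list(t.exons)
            i = rng.randrange(len(exons) - 1)
            gap = exons[i + 1].start - exons[i].end
            delta = rng.randint(1, max(1, gap // 2))
            exons[i] = GenomicInterval(
                exons[i].chrom, exons[i].start, exons[i].end + delta, exons[i].strand
            )
            out.append(Transcript(t.transcript_id, t.gene_id, tuple(exons)))
        else:
            out.append(Transcript(t.transcript_id, t.gene_id, t.exons))
    for j in range(rng.randint(0, 4)):  # spurious additions
        pos = rng.randint(0, 120_000)
        out.append(
            tx(f"extra{j}", f"extrag{j}", rng.choice(("chr1", "chr2")),
               rng.choice("+-"), (pos, pos + rng.randint(80, 500)))
        )
    return AnnotationSet.from_transcripts(out)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def orf_oracle(seq: str, min_aa: int):
    """Exhaustive ATG->stop enumeration; returns (frame, start, end,
    protein, complete3) tuples sorted like find_orfs."""
    from Bio.Seq import Seq

    stops = {"TAA", "TAG", "TGA"}
    seq = seq.upper()
    raw = []
    for p in range(len(seq) - 2):
        if seq[p : p + 3] != "ATG":
            continue
        q = p
        end = None
        complete3 = False
        while q + 3 <= len(seq):
            if seq[q : q + 3] in stops and q > p:
                end = q + 3
                complete3 = True
                break
            q += 3
        if end is None:
            end = p + 3 * ((len(seq) - p) // 3)
        if end > p:
            raw.append((p % 3, p, end, complete3))
    # keep the 5'-most ATG per (frame, end)
    best = {}
    for frame, start, end, c3 in raw:
        key = (frame, end)
        if key not in best or start < best[key][1]:
            best[key] = (frame, start, end, c3)
    out = []
    for frame, start, end, c3 in best.values():
        cds = seq[start : end - 3] if c3 else seq[start:end]
        protein = str(Seq(cds[: 3 * (len(cds) // 3)]).translate()).replace("*", "")
        if len(protein) >= min_aa:
            out.append((frame, start, end, protein, c3))
    out.sort(key=lambda o: (-len(o[3]), o[1]))
    return out


def overlap_oracle(annotation: AnnotationSet, query: GenomicInterval, same_strand):
    hits = [
        t
        for t in annotation.transcripts()
        if t.chrom == query.chrom
        and t.interval.start < query.end
        and query.start < t.interval.end
        and (not same_strand or (t.strand == query.strand and t.strand != "."))
    ]
    hits.sort(key=lambda t: (t.chrom, t.interval.start, t.transcript_id))
    return hits


def _base_sets(ts):
    out = set()
    for t in ts:
        for e in t.exons:
            for p in range(e.start, e.end):
                out.add((t.chrom, t.strand, p))
    return out


def _tx_match_oracle(a: Transcript, b: Transcript) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.is_multi_exon or b.is_multi_exon:
        return (
            a.is_multi_exon
            and b.is_multi_exon
            and a.intron_chain == b.intron_chain
        )
    ov = a.interval.overlap_bp(b.interval)
    return ov > 0 and min(ov / len(a.interval), ov / len(b.interval)) >= 0.8


def _loci_oracle(ts):
    """Connected components under same-strand exonic overlap (all pairs)."""
    n = len(ts)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ts[i], ts[j]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if any(ea.overlap_bp(eb) > 0 for ea in a.exons for eb in b.exons):
                adj[i][j] = adj[j][i] = True
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if adj[u][v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(comp)
    return comps


def evaluate_oracle(pred: AnnotationSet, ref: AnnotationSet):
    """All six levels by exhaustive enumeration; returns dict
    level -> (matched_pred, pred_total, matched_ref, ref_total)."""
    p = [t for t in pred.transcripts() if t.strand in "+-"]
    r = [t for t in ref.transcripts() if t.strand in "+-"]
    res = {}

    pb, rb = _base_sets(p), _base_sets(r)
    inter = len(pb & rb)
    res["base"] = (inter, len(pb), inter, len(rb))

    for level, what in (("exon", "exons"), ("intron", "introns")):
        ps = {(t.chrom, iv.start, iv.end, t.strand) for t in p for iv in getattr(t, what)}
        rs = {(t.chrom, iv.start, iv.end, t.strand) for t in r for iv in getattr(t, what)}
        res[level] = (len(ps & rs), len(ps), len(ps & rs), len(rs))

    pm = [t for t in p if t.is_multi_exon]
    rm = [t for t in r if t.is_multi_exon]
    rk = {(t.chrom, t.strand, t.intron_chain) for t in rm}
    pk = {(t.chrom, t.strand, t.intron_chain) for t in pm}
    res["intron_chain"] = (
        sum((t.chrom, t.strand, t.intron_chain) in rk for t in pm),
        len(pm),
        sum((t.chrom, t.strand, t.intron_chain) in pk for t in rm),
        len(rm),
    )

    p_match = [any(_tx_match_oracle(a, b) for b in r) for a in p]
    r_match = [any(_tx_match_oracle(b, a) for a in p) for b in r]
    res["transcript"] = (sum(p_match), len(p), sum(r_match), len(r))

    p_loci = _loci_oracle(p)
    r_loci = _loci_oracle(r)
    res["locus"] = (
        sum(any(p_match[i] for i in c) for c in p_loci),
        len(p_loci),
        sum(any(r_match[i] for i in c) for c in r_loci),
        len(r_loci),
    )
    return res


def exn50_oracle(records, fraction):
    """Literal prefix enumeration + N50 by scanning candidate lengths."""
    ranked = sorted(records, key=lambda x: (-x.tpm, -x.length, x.transcript_id))
    total = sum(x.tpm for x in records)
    prefix = []
    cum = 0.0
    for rec in ranked:
        prefix.append(rec)
        cum += rec.tpm
        if cum >= fraction * total - 1e-9:
            break
    lengths = [x.length for x in prefix]
    half = sum(lengths) / 2
    best = None
    for L in sorted(set(lengths), reverse=True):
        covered = sum(x for x in lengths if x >= L)
        if covered >= half:
            best = L  # keep descending: the largest qualifying L is first
            break
    return best, len(prefix)


# ---------------------------------------------------------------------------
# shared generated fixture
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_fixture():
    """One medium fixture shared by read-only tests."""
    return generate(
        FixtureSpec(
            seed=11, n_genes=10, chrom_length=900_000,
            paralog_pairs=2, paralog_gap=(50_000, 300_000), n_train=300,
        )
    )
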