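"""Seedable synthetic fixtures with complete ground truth.

Generates a toy genome, a reference annotation, a perturbed "assembly"
annotation, coding/noncoding training corpora, a quantification table
and a protein-hit table, together with a truth table recording every
planted feature's expected classification.  This is the test bed for
every downstream stage: reconciliation, coding/lncRNA classification,
homology calls and benchmarking.

Design of the planted signal:

* coding sequences are ATG + codons sampled from a biased codon
  distribution + stop; the bias magnitude (log-odds, default 0.3) is the
  hexamer signal the coding-potential classifier must recover;
* noncoding sequences are dinucleotide-preserving shuffles of
  coding-style sequences (same base/dinucleotide composition, no codon
  structure), regenerated until they carry no ORF long enough to qualify
  as coding, so the planted label is well defined;
* paralog-pair proteins are copies mutated by substitutions only, making
  percent identity exact by construction, and their loci are placed at a
  controlled genomic gap so the distance rule's truth is known.

All randomness flows from one seed; equal seeds give byte-identical
output files.
"""
from __future__ import annotations

import bisect
import itertools
import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .coding import dinucleotide_shuffle, find_orfs
from .core import AnnotationSet, GenomicInterval, Transcript
from .io import (
    BlastHit, QuantRecord, write_blast_tab, write_fasta, write_gtf, write_quant,
)

log = logging.getLogger("annotrec")

OVERLAP_GAP = -1  # sentinel: place the subject locus overlapping the query

SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class PlacementError(RuntimeError):
    """The requested features do not fit on the configured chromosomes."""


@dataclass(frozen=True)
class Perturbations:
    """Counts of planted deviations between assembly and reference."""

    novel_isoform: int = 2
    novel_intergenic_coding: int = 2
    novel_intergenic_noncoding: int = 2
    antisense_lnc: int = 1
    divergent_lnc: int = 1
    exon_shift: int = 2
    transcript_drop: int = 2

    @property
    def total(self) -> int:
        return sum(vars(self).values())


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study fixture."""

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 1_500_000
    n_genes: int = 20
    exon_count: tuple[int, int] = (1, 6)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (300, 2_000)
    intergenic_gap: tuple[int, int] = (25_000, 60_000)
    lnc_exon_count: tuple[int, int] = (1, 3)
    lnc_exon_length: tuple[int, int] = (300, 700)
    hexamer_bias: float = 0.3
    min_orf_aa: int = 100  # planted noncoding carry no ORF of this size
    perturbations: Perturbations = Perturbations()
    paralog_pairs: int = 2
    paralog_identity: tuple[float, float] = (92.0, 98.0)
    paralog_gap: tuple[int, int] = (50_000, 400_000)
    # explicit (identity%, gap bp) cases override the two ranges above;
    # gap == OVERLAP_GAP places the subject on top of the query locus
    homology_cases: tuple[tuple[float, int], ...] | None = None
    n_train: int = 1_000
    train_codons: tuple[int, int] = (150, 350)


@dataclass
class TruthTable:
    """Ground truth for every planted feature."""

    match_class: dict[str, str] = field(default_factory=dict)
    assigned_gene: dict[str, str] = field(default_factory=dict)
    coding_label: dict[str, str] = field(default_factory=dict)
    lncrna: dict[str, dict] = field(default_factory=dict)
    homology: dict[str, str] = field(default_factory=dict)


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: dict[str, str]
    reference: AnnotationSet
    assembly: AnnotationSet
    coding_train: dict[str, str]
    noncoding_train: dict[str, str]
    quant: list[QuantRecord]
    blast_hits: list[BlastHit]
    query_loci: dict[str, GenomicInterval]
    subject_loci: dict[str, GenomicInterval]
    truth: TruthTable

    def write(self, outdir) -> None:
        """Write all fixture files (plain text, deterministic order)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_gtf(self.reference, outdir / "reference.gtf", source_tag="annotrec_sim")
        write_gtf(self.assembly, outdir / "assembly.gtf", source_tag="annotrec_sim")
        write_fasta(self.coding_train, outdir / "train_coding.fa")
        write_fasta(self.noncoding_train, outdir / "train_noncoding.fa")
        write_quant(self.quant, outdir / "quant.sf")
        write_blast_tab(self.blast_hits, outdir / "blastp.tsv")
        with open(outdir / "subject_loci.tsv", "w") as fh:
            fh.write("protein\tchrom\tstart\tend\n")
            for pid, iv in self.subject_loci.items():
                fh.write(f"{pid}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("transcript_id\tmatch_class\tassigned_gene\tcoding_label\n")
            for tid in sorted(self.truth.match_class):
                fh.write(
                    f"{tid}\t{self.truth.match_class[tid]}\t"
                    f"{self.truth.assigned_gene.get(tid, '')}\t"
                    f"{self.truth.coding_label.get(tid, '')}\n"
                )
        with open(outdir / "homology_truth.tsv", "w") as fh:
            fh.write("query\texpected_call\n")
            for qid in sorted(self.truth.homology):
                fh.write(f"{qid}\t{self.truth.homology[qid]}\n")


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

class CodonBias:
    """First-order Markov model over sense codons with +-``bias`` log-odds
    transition weights (signs drawn once per fixture).

    Planting the bias in codon *transitions* rather than marginal codon
    frequencies puts the signal where a hexamer model reads it: adjacent
    codon pairs.  A dinucleotide-preserving shuffle keeps the marginal
    base composition (which carries little of this signal) while erasing
    the dicodon structure, so the planted coding/noncoding contrast is a
    genuine hexamer contrast.
    """

    def __init__(self, rng: random.Random, bias: float):
        self.bias = bias
        self._cum: dict[str, list[float]] = {}
        for c1 in SENSE_CODONS:
            acc, total = [], 0.0
            for _ in SENSE_CODONS:
                total += math.exp(bias if rng.random() < 0.5 else -bias)
                acc.append(total)
            self._cum[c1] = [a / total for a in acc]

    def next_codon(self, rng: random.Random, prev: str) -> str:
        return SENSE_CODONS[bisect.bisect(self._cum[prev], rng.random())]


def random_coding_sequence(
    rng: random.Random, bias: CodonBias, n_codons: int
) -> str:
    """ATG + ``n_codons`` Markov-sampled sense codons + one stop codon."""
    out = [rng.choice(SENSE_CODONS)]
    for _ in range(n_codons - 1):
        out.append(bias.next_codon(rng, out[-1]))
    return "ATG" + "".join(out[:n_codons]) + rng.choice(("TAA", "TAG", "TGA"))


def random_noncoding_sequence(
    rng: random.Random, weights: CodonBias, length: int, max_orf_aa: int
) -> str:
    """A noncoding sequence of ``length`` nt: the dinucleotide shuffle of
    a coding-style sequence, regenerated until no ORF of ``max_orf_aa``
    or more remains (so the planted noncoding label is unambiguous)."""
    n_codons = max(1, length // 3 - 2)
    for _ in range(100):
        seq = dinucleotide_shuffle(
            random_coding_sequence(rng, weights, n_codons), rng
        )
        seq = (seq * (length // len(seq) + 1))[:length] if len(seq) < length else seq[:length]
        if not find_orfs(seq, min_aa=max_orf_aa):
            return seq
    raise PlacementError("could not generate an ORF-free noncoding sequence")


def classification_corpus(
    seed: int,
    n_coding: int = 100,
    n_noncoding: int = 100,
    hexamer_bias: float = 0.3,
    min_orf_aa: int = 100,
    n_train: int = 1_000,
    train_codons: tuple[int, int] = (150, 350),
    test_codons: tuple[int, int] = (120, 400),
    noncoding_length: tuple[int, int] = (600, 1_500),
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Training corpus plus a labelled test set for coding classification.

    Returns (training coding sequences, test sequences, truth labels);
    truth is ``coding`` for planted mRNAs and ``lncRNA`` for planted
    noncoding transcripts.  Lengths mirror typical mRNA CDS and lncRNA
    sizes.
    """
    rng = random.Random(seed)
    bias = CodonBias(rng, hexamer_bias)
    train = {
        f"train_{i + 1}": random_coding_sequence(rng, bias, rng.randint(*train_codons))
        for i in range(n_train)
    }
    seqs: dict[str, str] = {}
    truth: dict[str, str] = {}
    for i in range(n_coding):
        tid = f"cod_{i + 1}"
        seqs[tid] = random_coding_sequence(rng, bias, rng.randint(*test_codons))
        truth[tid] = "coding"
    for i in range(n_noncoding):
        tid = f"non_{i + 1}"
        seqs[tid] = random_noncoding_sequence(
            rng, bias, rng.randint(*noncoding_length), min_orf_aa
        )
        truth[tid] = "lncRNA"
    return train, seqs, truth


def _mutate_protein(rng: random.Random, protein: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` positions (never to the same residue)."""
    positions = rng.sample(range(len(protein)), n_subs)
    out = list(protein)
    for p in positions:
        out[p] = rng.choice([a for a in AMINO_ACIDS if a != out[p]])
    return "".join(out)


def percent_identity(a: str, b: str) -> float:
    """Position-wise identity of two equal-length sequences, in percent."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# placement machinery
# ---------------------------------------------------------------------------

class _Occupancy:
    """Per-chromosome list of occupied intervals with a margin."""

    def __init__(self, chrom_lengths: dict[str, int], margin: int = 500):
        self.chrom_lengths = chrom_lengths
        self.margin = margin
        self.taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def add(self, chrom: str, start: int, end: int) -> None:
        self.taken[chrom].append((start, end))

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        if start < self.margin or end > self.chrom_lengths[chrom] - self.margin:
            return False
        return all(
            not (start - self.margin < te and ts < end + self.margin)
            for ts, te in self.taken[chrom]
        )

    def place(self, rng: random.Random, length: int, tries: int = 2000) -> tuple[str, int]:
        chroms = sorted(self.chrom_lengths)
        for _ in range(tries):
            chrom = rng.choice(chroms)
            hi = self.chrom_lengths[chrom] - length - self.margin
            if hi <= self.margin:
                continue
            start = rng.randint(self.margin, hi)
            if self.is_free(chrom, start, start + length):
                self.add(chrom, start, start + length)
                return chrom, start
        raise PlacementError(
            f"no free slot of {length} bp after {tries} tries "
            f"({sum(len(v) for v in self.taken.values())} features placed)"
        )


def _exon_layout(
    rng: random.Random,
    spec: FixtureSpec,
    coding: bool,
) -> tuple[list[int], list[int]]:
    """(exon lengths, intron lengths); coding layouts are padded so the
    total is a codon multiple long enough for the minimum protein, and
    noncoding (lncRNA-style) layouts use their own, longer exon ranges."""
    if coding:
        n = rng.randint(*spec.exon_count)
        exons = [rng.randint(*spec.exon_length) for _ in range(n)]
        total = sum(exons)
        need = 3 * (spec.min_orf_aa + 20)  # headroom above the ORF cutoff
        if total < need:
            exons[-1] += need - total
        exons[-1] += (3 - sum(exons) % 3) % 3
    else:
        n = rng.randint(*spec.lnc_exon_count)
        exons = [rng.randint(*spec.lnc_exon_length) for _ in range(n)]
    introns = [rng.randint(*spec.intron_length) for _ in range(n - 1)]
    return exons, introns


def _build_exons(
    chrom: str, start: int, strand: str, exon_lengths: list[int], intron_lengths: list[int]
) -> tuple[GenomicInterval, ...]:
    out = []
    pos = start
    for i, elen in enumerate(exon_lengths):
        out.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return tuple(out)


def _plant(genome: dict[str, bytearray], t: Transcript, spliced: str) -> None:
    """Write ``spliced`` into the genome so that extracting ``t`` returns it."""
    if t.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    pos = 0
    for e in t.exons:
        genome[t.chrom][e.start : e.end] = spliced[pos : pos + len(e)].encode()
        pos += len(e)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(spec: FixtureSpec, outdir=None) -> Fixture:
    """Generate the full fixture; optionally write it under ``outdir``."""
    rng = random.Random(spec.seed)
    weights = CodonBias(rng, spec.hexamer_bias)
    chrom_lengths = {
        f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)
    }
    genome = {
        c: bytearray(
            "".join(rng.choices("ACGT", k=n)).encode()
        )
        for c, n in chrom_lengths.items()
    }
    occ = _Occupancy(chrom_lengths)
    truth = TruthTable()

    # ---- reference genes, placed sequentially with intergenic gaps -------
    ref_transcripts: list[Transcript] = []
    symbols: dict[str, str] = {}
    chrom_cursor = {c: 20_000 for c in chrom_lengths}
    chrom_cycle = sorted(chrom_lengths)
    ci = 0
    for gi in range(spec.n_genes):
        exon_lengths, intron_lengths = _exon_layout(rng, spec, coding=True)
        span_len = sum(exon_lengths) + sum(intron_lengths)
        placed = False
        for _ in range(spec.n_chroms):
            chrom = chrom_cycle[ci % spec.n_chroms]
            ci += 1
            start = chrom_cursor[chrom]
            if start + span_len + 20_000 < chrom_lengths[chrom]:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"only {gi} of {spec.n_genes} genes fit on the genome"
            )
        strand = rng.choice("+-")
        gid = f"gene{gi + 1}"
        symbols[gid] = f"SYM{gi + 1}"
        tid = f"NM_{gi + 1:06d}"
        exons = _build_exons(chrom, start, strand, exon_lengths, intron_lengths)
        t = Transcript(tid, gid, exons)
        cds = random_coding_sequence(rng, weights, sum(exon_lengths) // 3 - 2)
        _plant(genome, t, cds)
        ref_transcripts.append(t)
        occ.add(chrom, start, start + span_len)
        chrom_cursor[chrom] = start + span_len + rng.randint(*spec.intergenic_gap)
    reference = AnnotationSet.from_transcripts(ref_transcripts, symbols)

    # ---- assembly: identity copy, then perturbations ---------------------
    pert = spec.perturbations
    pristine = pert.total == 0 and spec.paralog_pairs == 0 and not spec.homology_cases
    if pristine:
        assembly = AnnotationSet.from_transcripts(
            [Transcript(t.transcript_id, t.gene_id, t.exons) for t in ref_transcripts],
            symbols,
        )
        for t in ref_transcripts:
            truth.match_class[t.transcript_id] = "exact"
            truth.assigned_gene[t.transcript_id] = symbols[t.gene_id]
        asm_transcripts = list(assembly.transcripts())
    else:
        asm_transcripts = _perturb(
            rng, spec, weights, genome, occ, reference, symbols, truth
        )
        assembly = AnnotationSet.from_transcripts(asm_transcripts)

    # ---- homology fixture -------------------------------------------------
    blast_hits, query_loci, subject_loci = _homology_fixture(
        rng, spec, weights, genome, occ, chrom_lengths, asm_transcripts, truth
    )
    if not pristine:
        assembly = AnnotationSet.from_transcripts(asm_transcripts)

    # ---- training corpora and quantification ------------------------------
    coding_train = {}
    noncoding_train = {}
    for i in range(spec.n_train):
        seq = random_coding_sequence(rng, weights, rng.randint(*spec.train_codons))
        coding_train[f"train_cod_{i + 1}"] = seq
        noncoding_train[f"train_non_{i + 1}"] = dinucleotide_shuffle(seq, rng)

    genome_str = {c: bytes(b).decode() for c, b in genome.items()}
    raw = [rng.expovariate(1.0) for _ in asm_transcripts]
    total = sum(raw)
    quant = [
        QuantRecord(t.transcript_id, t.spliced_length, round(1e6 * w / total, 6))
        for t, w in zip(asm_transcripts, raw)
    ]

    fx = Fixture(
        spec=spec,
        genome=genome_str,
        reference=reference,
        assembly=assembly,
        coding_train=coding_train,
        noncoding_train=noncoding_train,
        quant=quant,
        blast_hits=blast_hits,
        query_loci=query_loci,
        subject_loci=subject_loci,
        truth=truth,
    )
    if outdir is not None:
        fx.write(outdir)
    log.info(
        "generated fixture seed=%d: %d ref genes, %d assembly transcripts",
        spec.seed, len(reference), assembly.n_transcripts,
    )
    return fx


def _perturb(
    rng, spec, weights, genome, occ, reference, symbols, truth
) -> list[Transcript]:
    """Relabel reference transcripts as assembler output and apply the
    requested perturbations; records truth as it goes."""
    pert = spec.perturbations
    base = list(reference.transcripts())
    dropped = set()
    if pert.transcript_drop:
        if pert.transcript_drop > len(base):
            raise PlacementError("more drops requested than transcripts")
        dropped = {
            t.transcript_id for t in rng.sample(base, pert.transcript_drop)
        }
    kept = [t for t in base if t.transcript_id not in dropped]

    shifted: dict[str, Transcript] = {}
    multi = [t for t in kept if t.is_multi_exon]
    if pert.exon_shift > len(multi):
        raise PlacementError("not enough multi-exon transcripts to shift")
    for t in rng.sample(multi, pert.exon_shift):
        shifted[t.transcript_id] = _shift_boundary(rng, t)

    out: list[Transcript] = []
    counter = 0
    for t in kept:
        counter += 1
        tid = f"STRG.{counter}.1"
        gid = f"STRG.{counter}"
        src = shifted.get(t.transcript_id, t)
        out.append(Transcript(tid, gid, src.exons))
        if t.transcript_id in shifted:
            truth.match_class[tid] = "isoform"
        else:
            truth.match_class[tid] = "exact"
        truth.assigned_gene[tid] = symbols[t.gene_id]

    def new_ids():
        nonlocal counter
        counter += 1
        return f"STRG.{counter}.1", f"STRG.{counter}"

    # extra isoforms of annotated genes (exon skip, else boundary shift)
    skippable = [t for t in base if len(t.exons) >= 3]
    for _ in range(pert.novel_isoform):
        src = rng.choice(skippable if skippable else multi)
        tid, gid = new_ids()
        if len(src.exons) >= 3:
            drop_i = rng.randrange(1, len(src.exons) - 1)
            exons = tuple(e for i, e in enumerate(src.exons) if i != drop_i)
        else:
            exons = _shift_boundary(rng, src).exons
        out.append(Transcript(tid, gid, exons))
        truth.match_class[tid] = "isoform"
        truth.assigned_gene[tid] = symbols[src.gene_id]

    # novel intergenic transcripts, coding and noncoding
    for kind, count in (
        ("coding", pert.novel_intergenic_coding),
        ("lncRNA", pert.novel_intergenic_noncoding),
    ):
        for _ in range(count):
            exon_lengths, intron_lengths = _exon_layout(
                rng, spec, coding=(kind == "coding")
            )
            span_len = sum(exon_lengths) + sum(intron_lengths)
            chrom, start = occ.place(rng, span_len)
            strand = rng.choice("+-")
            tid, gid = new_ids()
            t = Transcript(tid, gid, _build_exons(chrom, start, strand, exon_lengths, intron_lengths))
            if kind == "coding":
                seq = random_coding_sequence(rng, weights, sum(exon_lengths) // 3 - 2)
            else:
                seq = random_noncoding_sequence(
                    rng, weights, sum(exon_lengths), spec.min_orf_aa
                )
            _plant(genome, t, seq)
            out.append(t)
            truth.match_class[tid] = "novel_intergenic"
            truth.assigned_gene[tid] = gid
            truth.coding_label[tid] = kind

    # antisense lncRNAs: one exon copied from a reference gene, strand flipped
    ref_list = list(reference.transcripts())
    for _ in range(pert.antisense_lnc):
        src = rng.choice(ref_list)
        exon = rng.choice(src.exons)
        tid, gid = new_ids()
        flipped = "-" if src.strand == "+" else "+"
        t = Transcript(
            tid, gid, (GenomicInterval(exon.chrom, exon.start, exon.end, flipped),)
        )
        out.append(t)
        truth.match_class[tid] = "novel_antisense"
        truth.assigned_gene[tid] = gid
        truth.lncrna[tid] = {
            "relation": "genic",
            "direction": "antisense",
            "location": "exonic",
            "partner": symbols[src.gene_id],
        }

    # divergent lncRNAs: head-to-head upstream of a reference gene
    for _ in range(pert.divergent_lnc):
        t, partner_gid = _place_divergent(rng, spec, occ, reference, new_ids)
        seq = random_noncoding_sequence(
            rng, weights, t.spliced_length, spec.min_orf_aa
        )
        _plant(genome, t, seq)
        out.append(t)
        truth.match_class[t.transcript_id] = "novel_intergenic"
        truth.assigned_gene[t.transcript_id] = t.gene_id
        truth.coding_label[t.transcript_id] = "lncRNA"
        truth.lncrna[t.transcript_id] = {
            "relation": "intergenic",
            "direction": "antisense",
            "location": "upstream",
            "subtype": "divergent",
            "partner": symbols[partner_gid],
        }
    return out


def _shift_boundary(rng: random.Random, t: Transcript) -> Transcript:
    """Move one internal exon boundary into its intron (new intron chain)."""
    i = rng.randrange(len(t.introns))
    intron = t.introns[i]
    delta = rng.randint(10, max(10, min(50, len(intron) - 10)))
    exons = list(t.exons)
    e = exons[i]
    exons[i] = GenomicInterval(e.chrom, e.start, e.end + delta, e.strand)
    return Transcript(t.transcript_id, t.gene_id, tuple(exons))


def _place_divergent(rng, spec, occ, reference, new_ids):
    genes = sorted(reference.genes.values(), key=lambda g: g.gene_id)
    rng.shuffle(genes)
    for gene in genes:
        span = gene.span
        gap = rng.randint(1_000, 5_000)
        length = rng.randint(600, 1_200)
        if gene.strand == "+":
            start, strand = span.start - gap - length, "-"
        else:
            start, strand = span.end + gap, "+"
        end = start + length
        if start < 0 or not occ.is_free(span.chrom, start, end):
            continue
        # the partner must stay the nearest gene
        ok = True
        for other in reference.genes.values():
            if other.gene_id == gene.gene_id or other.chrom != span.chrom:
                continue
            if other.span.gap(GenomicInterval(span.chrom, start, end)) <= gap:
                ok = False
                break
        if not ok:
            continue
        occ.add(span.chrom, start, end)
        tid, gid = new_ids()
        return (
            Transcript(tid, gid, (GenomicInterval(span.chrom, start, end, strand),)),
            gene.gene_id,
        )
    raise PlacementError("no upstream slot for a divergent lncRNA")


def _homology_fixture(
    rng, spec, weights, genome, occ, chrom_lengths, asm_transcripts, truth
):
    """Plant paralog-pair queries as novel coding transcripts and emit the
    protein-hit table plus query/subject locus maps."""
    cases = spec.homology_cases
    if cases is None:
        cases = tuple(
            (rng.uniform(*spec.paralog_identity), rng.randint(*spec.paralog_gap))
            for _ in range(spec.paralog_pairs)
        )
    hits: list[BlastHit] = []
    query_loci: dict[str, GenomicInterval] = {}
    subject_loci: dict[str, GenomicInterval] = {}
    next_id = max(
        (int(t.gene_id.split(".")[1]) for t in asm_transcripts
         if t.gene_id.startswith("STRG.")),
        default=0,
    )
    for i, (identity, gap) in enumerate(cases, start=1):
        # the query is itself a planted coding transcript: its CDS comes
        # from the biased codon chain, the protein by translation
        cds = random_coding_sequence(rng, weights, rng.randint(150, 300))
        protein = str(Seq(cds[:-3]).translate())
        n_subs = round((1 - identity / 100) * len(protein))
        subject = _mutate_protein(rng, protein, n_subs)
        pident = percent_identity(protein, subject)
        # lay the query out as a single-exon novel gene with room for the
        # subject locus downstream at the requested gap
        qlen = len(cds)
        need = qlen + (gap if gap != OVERLAP_GAP else 0) + qlen + 2_000
        chrom, start = _place_with_room(rng, occ, chrom_lengths, qlen, need)
        next_id += 1
        tid, gid = f"STRG.{next_id}.1", f"STRG.{next_id}"
        t = Transcript(tid, gid, (GenomicInterval(chrom, start, start + qlen, "+"),))
        _plant(genome, t, cds)
        asm_transcripts.append(t)
        truth.match_class[tid] = "novel_intergenic"
        truth.assigned_gene[tid] = gid
        truth.coding_label[tid] = "coding"

        qspan = t.interval
        sid = f"SUBJ.{i}"
        if gap == OVERLAP_GAP:
            sspan = GenomicInterval(chrom, qspan.start + qlen // 2, qspan.end + qlen // 2)
        else:
            sspan = GenomicInterval(chrom, qspan.end + gap, qspan.end + gap + qlen)
        # the identity band is tested before any locus geometry
        if pident < 90.0:
            expected = "dropped"
        elif gap == OVERLAP_GAP:
            expected = "missing_gene_isoform"
        elif gap < 500_000:
            expected = "paralog"
        else:
            expected = "homolog_missing_gene"
        query_loci[tid] = qspan
        subject_loci[sid] = sspan
        L = len(protein)
        hits.append(
            BlastHit(
                qseqid=tid, sseqid=sid, pident=round(pident, 3), length=L,
                mismatch=n_subs, gapopen=0, qstart=1, qend=L, sstart=1, send=L,
                evalue=1e-100, bitscore=round(2.0 * L, 1),
            )
        )
        truth.homology[tid] = expected
    return hits, query_loci, subject_loci


def _place_with_room(rng, occ, chrom_lengths, length, room):
    """Place ``length`` bp such that ``room`` bp fit before the chromosome
    end (the virtual subject locus must stay on-chromosome)."""
    for _ in range(2000):
        chrom = rng.choice(sorted(chrom_lengths))
        hi = chrom_lengths[chrom] - room - occ.margin
        if hi <= occ.margin:
            continue
        start = rng.randint(occ.margin, hi)
        if occ.is_free(chrom, start, start + length):
            occ.add(chrom, start, start + length)
            return chrom, start
    raise PlacementError(f"no slot with {room} bp of downstream room")
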