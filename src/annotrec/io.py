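"""Readers and writers for the plain-text formats the pipeline consumes.

GTF (1-based inclusive on disk, 0-based half-open in memory), FASTA,
BLAST tabular ``outfmt 6`` and Salmon-style quantification tables.
Both GTF dialects seen in practice are accepted: assembler output
(``STRG`` ids, no ``gene_name``) and reference annotation
(``gene_name`` present, e.g. ncbiRefSeq).
"""
from __future__ import annotations

import csv
import logging
import sys
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .core import AnnotationSet, Gene, GenomicInterval, Transcript

log = logging.getLogger("annotrec")


def configure_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the given level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path, self.lineno = str(path), lineno
        super().__init__(f"{path}:{lineno}: {message}")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path) -> AnnotationSet:
    """Parse a GTF file into an :class:`AnnotationSet`.

    Only ``exon`` and ``transcript`` features are consulted; both must
    carry ``gene_id`` and ``transcript_id`` attributes.  Coordinates are
    converted to 0-based half-open.  The gene symbol is the ``gene_name``
    attribute when present, else the ``gene_id``.  Files with exon rows
    but no transcript rows (StringTie style) are accepted: the transcript
    is synthesised from its exon set.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    symbols: dict[str, str] = {}
    tx_order: list[str] = []
    tx_span: dict[str, GenomicInterval] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # malformed column structure
                raise ParseError(path, lineno, f"unparseable GTF line ({exc})")
            if feat.featuretype not in ("exon", "transcript"):
                continue
            if feat.end < feat.start:
                raise ParseError(path, lineno, f"end {feat.end} < start {feat.start}")
            attrs = feat.attributes
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ParseError(
                    path, lineno, "missing mandatory gene_id/transcript_id attribute"
                )
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0]
            prev_gid = gene_of.setdefault(tid, gid)
            if prev_gid != gid:
                raise ParseError(
                    path, lineno, f"transcript {tid} under two gene_ids"
                )
            if "gene_name" in attrs:
                symbols.setdefault(gid, attrs["gene_name"][0])
            if tid not in exons:
                exons[tid] = []
                tx_order.append(tid)
            iv = GenomicInterval(
                feat.seqid, feat.start - 1, feat.end, feat.strand or "."
            )
            if feat.featuretype == "exon":
                exons[tid].append(iv)
            else:
                tx_span[tid] = iv

    transcripts = []
    for tid in tx_order:
        evs = exons[tid] or [tx_span[tid]]  # transcript row without exon rows
        transcripts.append(Transcript(tid, gene_of[tid], tuple(evs)))
    annotation = AnnotationSet.from_transcripts(transcripts, symbols)
    log.info(
        "read %s: %d genes, %d transcripts",
        path, len(annotation), annotation.n_transcripts,
    )
    return annotation


def write_gtf(
    annotation: AnnotationSet,
    path,
    source_tag: str = "annotrec",
    extra_attributes: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write an :class:`AnnotationSet` as GTF (1-based inclusive).

    Each transcript row precedes its exon rows.  Attribute order is fixed
    (gene_id, transcript_id, gene_name, then any extras sorted by key) so
    equal annotations produce byte-identical files.  ``extra_attributes``
    maps transcript_id to additional key/value pairs for transcript rows.
    """
    extra_attributes = extra_attributes or {}
    genes = sorted(
        annotation.genes.values(), key=lambda g: (g.chrom, g.span.start, g.gene_id)
    )
    with open(path, "w") as out:
        for gene in genes:
            for t in sorted(
                gene.transcripts,
                key=lambda t: (t.interval.start, t.transcript_id),
            ):
                pairs = [("gene_id", gene.gene_id), ("transcript_id", t.transcript_id)]
                if gene.symbol != gene.gene_id:
                    pairs.append(("gene_name", gene.symbol))
                pairs += sorted(extra_attributes.get(t.transcript_id, {}).items())
                attrs = " ".join(f'{k} "{v}";' for k, v in pairs)
                span = t.interval
                out.write(
                    f"{t.chrom}\t{source_tag}\ttranscript\t{span.start + 1}\t"
                    f"{span.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
                exon_attrs = " ".join(f'{k} "{v}";' for k, v in pairs[:3])
                for e in t.exons:
                    out.write(
                        f"{t.chrom}\t{source_tag}\texon\t{e.start + 1}\t{e.end}\t"
                        f".\t{t.strand}\t.\t{exon_attrs}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path) -> None:
    """Write sequences wrapped at 60 columns, in mapping order."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BLAST outfmt 6
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlastHit:
    """One row of tabular BLAST output (outfmt 6, optional 13th qcovs)."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qcov: float | None = None  # qcovs column; None when the file has 12 columns

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")


def read_blast_tab(path) -> list[BlastHit]:
    """Parse 12- or 13-column tabular BLAST output, preserving file order.

    No best-hit selection happens here; that policy lives in
    :mod:`annotrec.homology`.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) not in (12, 13):
                raise ParseError(
                    path, lineno, f"expected 12 or 13 columns, found {len(row)}"
                )
            try:
                hit = BlastHit(
                    qseqid=row[0],
                    sseqid=row[1],
                    pident=float(row[2]),
                    length=int(row[3]),
                    mismatch=int(row[4]),
                    gapopen=int(row[5]),
                    qstart=int(row[6]),
                    qend=int(row[7]),
                    sstart=int(row[8]),
                    send=int(row[9]),
                    evalue=float(row[10]),
                    bitscore=float(row[11]),
                    qcov=float(row[12]) if len(row) == 13 else None,
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path) -> None:
    with open(path, "w") as out:
        for h in hits:
            cols = [
                h.qseqid, h.sseqid, f"{h.pident:.3f}", h.length, h.mismatch,
                h.gapopen, h.qstart, h.qend, h.sstart, h.send,
                f"{h.evalue:.2e}", f"{h.bitscore:.1f}",
            ]
            if h.qcov is not None:
                cols.append(f"{h.qcov:.1f}")
            out.write("\t".join(str(c) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# Quantification tables (quant.sf dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantRecord:
    transcript_id: str
    length: int
    tpm: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"non-positive length {self.length}")
        if self.tpm < 0:
            raise ValueError(f"negative TPM {self.tpm}")


_NAME_COLS = {"name", "transcript_id", "transcript", "id"}


def read_quant(path) -> list[QuantRecord]:
    """Read a TSV of transcript expression (Salmon ``quant.sf`` accepted).

    The header must name a transcript column (Name/transcript_id), a
    Length column and a TPM column; other columns are ignored.
    """
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(path, 1, "empty quantification table")
        lower = [h.strip().lower() for h in header]
        try:
            name_i = next(i for i, h in enumerate(lower) if h in _NAME_COLS)
            len_i = lower.index("length")
            tpm_i = lower.index("tpm")
        except (StopIteration, ValueError):
            raise ParseError(
                path, 1, f"header must name transcript, Length and TPM columns; got {header}"
            )
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                records.append(
                    QuantRecord(row[name_i], int(float(row[len_i])), float(row[tpm_i]))
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc))
    return records


def write_quant(records: Iterable[QuantRecord], path) -> None:
    with open(path, "w") as out:
        out.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
        for r in records:
            out.write(
                f"{r.transcript_id}\t{r.length}\t{r.length}\t{r.tpm:.6f}\t0.0\n"
            )
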