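"""End-to-end annotation run: reconcile -> classify -> lncRNA -> homology.

The :func:`annotate` entry point reads an assembled GTF, a reference GTF
and the genome, reconciles the assembly with the reference, classifies
every transcript as coding / lncRNA / other, positions lncRNAs relative
to coding genes, optionally assigns homology calls from a protein-hit
table, and writes a merged GTF plus machine-readable tables.  Each stage
is also exposed as a CLI subcommand; ``annotate`` equals their
composition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import coding as coding_mod
from . import homology as homology_mod
from . import lncrna as lncrna_mod
from .core import AnnotationSet, spliced_sequence
from .io import (
    read_blast_tab, read_fasta, read_gtf, write_fasta, write_gtf,
)
from .reconcile import reconcile_annotation, records_table

log = logging.getLogger("annotrec")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


class ConfigError(ValueError):
    """Invalid run configuration (missing input, threshold out of range)."""


@dataclass
class RunConfig:
    """Inputs, outputs and thresholds of one annotation run."""

    assembly_gtf: str
    reference_gtf: str
    genome_fa: str
    outdir: str
    train_coding_fa: str | None = None  # default: reference transcript sequences
    train_noncoding_fa: str | None = None  # default: seeded dinucleotide shuffles
    blast_tsv: str | None = None
    subject_loci_tsv: str | None = None
    min_aa: int = coding_mod.DEFAULT_MIN_AA
    score_threshold: float = coding_mod.DEFAULT_SCORE_THRESHOLD
    min_identity: float = 90.0
    max_identity: float = 100.0
    locus_window: int = 500_000
    lnc_window: int = lncrna_mod.DEFAULT_WINDOW
    single_exon_overlap: float = 0.8
    evalue_max: float = 1e-5
    qcov_min: float = 10.0
    lncrna_first: bool = True
    seed: int = 1

    def validate(self) -> None:
        for label, path in (
            ("assembly GTF", self.assembly_gtf),
            ("reference GTF", self.reference_gtf),
            ("genome FASTA", self.genome_fa),
        ):
            if not Path(path).is_file():
                raise ConfigError(f"{label} not found: {path}")
        for label, path in (
            ("training FASTA", self.train_coding_fa),
            ("noncoding FASTA", self.train_noncoding_fa),
            ("protein hits", self.blast_tsv),
            ("subject loci", self.subject_loci_tsv),
        ):
            if path is not None and not Path(path).is_file():
                raise ConfigError(f"{label} not found: {path}")
        if self.min_aa < 1:
            raise ConfigError("min_aa must be >= 1")
        if not (0 < self.single_exon_overlap <= 1):
            raise ConfigError("single_exon_overlap must lie in (0, 1]")
        if not (0 <= self.min_identity <= self.max_identity <= 100):
            raise ConfigError("identity bounds must satisfy 0 <= min <= max <= 100")
        if self.locus_window <= 0 or self.lnc_window <= 0:
            raise ConfigError("windows must be positive")


@dataclass
class AnnotateResult:
    reconciled: AnnotationSet
    records: list
    classes: list
    proteins: dict[str, str]
    lnc_classes: list
    homology_calls: list
    homology_dropped: list
    summary: dict[tuple[str, str], int] = field(default_factory=dict)


def read_subject_loci(path) -> dict:
    """Sidecar TSV of subject loci: protein, chrom, start, end (0-based
    half-open).  Used for proteins whose gene is absent from the GTF."""
    from .core import GenomicInterval

    out = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("protein"):
            raise ConfigError(f"unexpected subject-loci header: {header!r}")
        for line in fh:
            name, chrom, start, end = line.rstrip("\n").split("\t")
            out[name] = GenomicInterval(chrom, int(start), int(end))
    return out


def annotate(config: RunConfig) -> AnnotateResult:
    """Run the full downstream flow and write all outputs under
    ``config.outdir``.  On any stage failure, partial outputs are removed
    and a :class:`StageError` naming the stage is raised."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _annotate(config, outdir, written)
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _annotate(config: RunConfig, outdir: Path, written: list[Path]) -> AnnotateResult:
    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    assembly = _stage("read_assembly", read_gtf, config.assembly_gtf)
    reference = _stage("read_reference", read_gtf, config.reference_gtf)
    genome = _stage("read_genome", read_fasta, config.genome_fa)

    reconciled, records = _stage(
        "reconcile", reconcile_annotation, assembly, reference,
        config.single_exon_overlap,
    )

    # training corpus: supplied FASTA, else known coding transcripts
    def _train():
        if config.train_coding_fa:
            cod = list(read_fasta(config.train_coding_fa).values())
        else:
            cod = [
                spliced_sequence(t, genome) for t in reference.transcripts()
            ]
        non = (
            list(read_fasta(config.train_noncoding_fa).values())
            if config.train_noncoding_fa
            else None
        )
        return coding_mod.train_hexamer(cod, non, seed=config.seed)

    model = _stage("train_hexamer", _train)

    sequences = _stage(
        "extract_sequences",
        lambda: {
            t.transcript_id: spliced_sequence(t, genome)
            for t in assembly.transcripts()
        },
    )
    hits = (
        _stage("read_hits", read_blast_tab, config.blast_tsv)
        if config.blast_tsv
        else None
    )
    classes, proteins = _stage(
        "classify", coding_mod.classify_novel, sequences, model, hits,
        config.min_aa, config.score_threshold, config.evalue_max,
        config.qcov_min, config.lncrna_first,
    )

    known = {r.transcript_id for r in records if r.match_class.is_known}
    label_of = {c.transcript_id: c.label for c in classes}
    lnc_novel = [
        assembly.transcript(c.transcript_id)
        for c in classes
        if c.label == "lncRNA" and c.transcript_id not in known
    ]
    lnc_classes = _stage(
        "lncclass", lncrna_mod.classify_all, lnc_novel, reference,
        config.lnc_window,
    )

    homology_calls, homology_dropped = [], []
    if hits:
        novel_coding = [
            c.transcript_id for c in classes
            if c.label == "coding" and c.transcript_id not in known
        ]
        best = homology_mod.best_hit_per_query(
            [h for h in hits if h.qseqid in set(novel_coding)]
        )
        query_loci = {
            tid: assembly.transcript(tid).interval for tid in best
        }
        subject_loci = {}
        for g in reference.genes.values():
            for t in g.transcripts:
                subject_loci[t.transcript_id] = g.span
            subject_loci.setdefault(g.symbol, g.span)
        if config.subject_loci_tsv:
            subject_loci.update(read_subject_loci(config.subject_loci_tsv))
        params = homology_mod.HomologyParams(
            config.min_identity, config.max_identity,
            config.locus_window, config.evalue_max,
        )
        homology_calls, homology_dropped = _stage(
            "homology", homology_mod.assign_homology,
            best, query_loci, subject_loci, params,
        )

    # ---- outputs ---------------------------------------------------------
    summary: dict[tuple[str, str], int] = {}
    for r in records:
        cat = "known" if r.match_class.is_known else "novel"
        key = (cat, label_of[r.transcript_id])
        summary[key] = summary.get(key, 0) + 1

    extra = {
        r.transcript_id: {
            "assigned_gene": r.assigned_gene,
            "match_class": r.match_class.value,
            "label": label_of[r.transcript_id],
        }
        for r in records
    }
    paths = {name: outdir / name for name in (
        "merged.gtf", "reconciliation.tsv", "classes.tsv", "proteins.fa",
        "lncclass.tsv", "homology.tsv", "summary.tsv",
    )}
    written.extend(paths.values())

    def _write_all():
        write_gtf(reconciled, paths["merged.gtf"], "annotrec", extra)
        paths["reconciliation.tsv"].write_text(records_table(records))
        lines = ["transcript_id\tlabel\tcoding_score\torf_coverage\thas_homology"]
        for c in classes:
            lines.append(
                f"{c.transcript_id}\t{c.label}\t{c.coding_score:.6f}\t"
                f"{c.orf_coverage:.6f}\t{int(c.has_homology)}"
            )
        paths["classes.tsv"].write_text("\n".join(lines) + "\n")
        write_fasta(proteins, paths["proteins.fa"])
        paths["lncclass.tsv"].write_text(lncrna_mod.lncrna_table(lnc_classes))
        paths["homology.tsv"].write_text(
            homology_mod.calls_table(homology_calls, homology_dropped)
        )
        rows = ["category\tlabel\tn_transcripts"]
        for cat in ("known", "novel"):
            for lab in ("coding", "lncRNA", "other"):
                rows.append(f"{cat}\t{lab}\t{summary.get((cat, lab), 0)}")
        paths["summary.tsv"].write_text("\n".join(rows) + "\n")

    _stage("write_outputs", _write_all)
    log.info("annotate finished: %s", dict(sorted(summary.items())))
    return AnnotateResult(
        reconciled=reconciled,
        records=records,
        classes=classes,
        proteins=proteins,
        lnc_classes=lnc_classes,
        homology_calls=homology_calls,
        homology_dropped=homology_dropped,
        summary=summary,
    )
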