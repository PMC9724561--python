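"""Reconciliation: the five-class matcher and annotation regrouping."""
import random

import pytest

from annotrec.core import AnnotationSet
from annotrec.reconcile import (
    MatchClass, match_transcript, reconcile_annotation,
)
from annotrec.simulate import FixtureSpec, generate
from conftest import tx


@pytest.fixture()
def reference():
    """Two genes: SSPO (3 exons, +) and a single-exon gene on chr1."""
    ts = [
        tx("NM_1", "g1", "chr1", "+", (1000, 1200), (1500, 1700), (2000, 2300)),
        tx("NM_2", "g2", "chr1", "+", (10_000, 10_800)),
        tx("NM_3", "g3", "chr1", "-", (30_000, 30_200), (31_000, 31_300)),
    ]
    return AnnotationSet.from_transcripts(
        ts, {"g1": "SSPO", "g2": "ALPHA", "g3": "BETA"}
    )


class TestMatchTranscript:
    def test_identical_intron_chain_is_exact(self, reference):
        t = tx("STRG.1.1", "STRG.1", "chr1", "+",
               (900, 1200), (1500, 1700), (2000, 2400))  # ends differ, chain equal
        rec = match_transcript(t, reference)
        assert rec.match_class is MatchClass.EXACT
        assert rec.assigned_gene == "SSPO"
        assert rec.ref_transcript_id == "NM_1"

    def test_single_exon_reciprocal_overlap_is_exact(self, reference):
        t = tx("STRG.2.1", "STRG.2", "chr1", "+", (10_050, 10_850))
        rec = match_transcript(t, reference)
        assert rec.match_class is MatchClass.EXACT
        assert rec.assigned_gene == "ALPHA"

    def test_single_exon_below_threshold_is_isoform(self, reference):
        # 400/800 reciprocal overlap: below the 80% bar, still exonic
        t = tx("STRG.3.1", "STRG.3", "chr1", "+", (10_400, 11_200))
        rec = match_transcript(t, reference)
        assert rec.match_class is MatchClass.ISOFORM

    def test_isoform_assigned_to_largest_exonic_overlap(self):
        ref = AnnotationSet.from_transcripts(
            [
                tx("rA", "gA", "chr1", "+", (100, 400)),
                tx("rB", "gB", "chr1", "+", (380, 700)),
            ],
            {"gA": "A", "gB": "B"},
        )
        t = tx("q", "STRG.9", "chr1", "+", (250, 420))  # 150 bp in A, 40 in B
        rec = match_transcript(t, ref)
        assert rec.match_class is MatchClass.ISOFORM
        assert rec.assigned_gene == "A"
        assert rec.overlap_bp == 150

    def test_intronic_same_strand_no_exon_overlap(self, reference):
        t = tx("STRG.4.1", "STRG.4", "chr1", "+", (1750, 1900))
        assert match_transcript(t, reference).match_class is MatchClass.NOVEL_INTRONIC

    def test_antisense_exonic_overlap(self, reference):
        t = tx("STRG.5.1", "STRG.5", "chr1", "+", (30_100, 30_400))
        assert match_transcript(t, reference).match_class is MatchClass.NOVEL_ANTISENSE

    def test_intergenic_keeps_assembler_gene_id(self, reference):
        t = tx("STRG.7.1", "STRG.7", "chr1", "+", (50_000, 50_500))
        rec = match_transcript(t, reference)
        assert rec.match_class is MatchClass.NOVEL_INTERGENIC
        assert rec.assigned_gene == "STRG.7"

    def test_exact_stays_known_under_isoform_relaxation(self, reference):
        """Any exact match would also qualify as an isoform (rule nesting)."""
        t = tx("STRG.1.1", "STRG.1", "chr1", "+",
               (1000, 1200), (1500, 1700), (2000, 2300))
        rec = match_transcript(t, reference)
        assert rec.match_class is MatchClass.EXACT
        gene = reference.genes["g1"]
        assert gene.exonic_overlap_bp(t) > 0  # isoform rule would fire too


class TestReconcileAnnotation:
    def test_identity_assembly_is_all_exact(self, reference):
        out, records = reconcile_annotation(reference, reference)
        assert len(records) == reference.n_transcripts
        assert all(r.match_class is MatchClass.EXACT for r in records)
        assert len(out) == len(reference)

    def test_conservation_and_grouping(self, reference):
        asm = AnnotationSet.from_transcripts(
            [
                tx("STRG.1.1", "STRG.1", "chr1", "+",
                   (1000, 1200), (1500, 1700), (2000, 2300)),
                tx("STRG.2.1", "STRG.2", "chr1", "+",
                   (1000, 1250), (1500, 1700), (2000, 2300)),
                tx("STRG.3.1", "STRG.3", "chr1", "+", (90_000, 90_500)),
            ]
        )
        out, records = reconcile_annotation(asm, reference)
        assert {r.transcript_id for r in records} == {
            "STRG.1.1", "STRG.2.1", "STRG.3.1"
        }
        # both known transcripts grouped under the reference gene
        assert {t.transcript_id for t in out.genes["g1"].transcripts} == {
            "STRG.1.1", "STRG.2.1"
        }
        assert "STRG.3" in out.genes
        assert out.n_transcripts == asm.n_transcripts

    def test_adding_reference_genes_never_unknowns(self, reference):
        asm = AnnotationSet.from_transcripts(
            [
                tx("a", "STRG.1", "chr1", "+", (1000, 1200), (1500, 1700)),
                tx("b", "STRG.2", "chr1", "-", (60_000, 60_400)),
            ]
        )
        _, before = reconcile_annotation(asm, reference)
        bigger = AnnotationSet.from_transcripts(
            [t for t in reference.transcripts()]
            + [tx("NM_9", "g9", "chr2", "+", (5_000, 5_600))],
            {"g1": "SSPO", "g2": "ALPHA", "g3": "BETA", "g9": "GAMMA"},
        )
        _, after = reconcile_annotation(asm, bigger)
        for r0, r1 in zip(before, after):
            if r0.match_class.is_known:
                assert r1.match_class.is_known

    def test_truth_recovery_on_generated_fixtures(self):
        for seed in (2, 5):
            fx = generate(
                FixtureSpec(seed=seed, n_genes=10, chrom_length=900_000,
                            paralog_pairs=1, paralog_gap=(50_000, 200_000),
                            n_train=5)
            )
            _, records = reconcile_annotation(fx.assembly, fx.reference)
            assert len(records) == fx.assembly.n_transcripts
            for r in records:
                assert r.match_class.value == fx.truth.match_class[r.transcript_id]
                assert r.assigned_gene == fx.truth.assigned_gene[r.transcript_id]
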