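"""Six-level evaluation and the expression-weighted N50."""
import random

import pytest

from annotrec.core import AnnotationSet
from annotrec.io import QuantRecord
from annotrec.metrics import LEVELS, evaluate, exn50, f1
from conftest import (
    evaluate_oracle, exn50_oracle, perturbed_copy, random_annotation, tx,
)


class TestF1:
    def test_closed_form(self):
        assert f1(1.0, 1.0) == 1.0
        assert f1(0.0, 0.7) == 0.0
        assert f1(0.8, 0.4) == pytest.approx(2 * 0.32 / 1.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            f1(1.2, 0.5)
        with pytest.raises(ValueError):
            f1(0.5, -0.1)


class TestEvaluate:
    def test_identity_is_perfect_at_all_levels(self):
        ann = random_annotation(random.Random(2), n_genes=15)
        for m in evaluate(ann, ann):
            assert m.precision == m.recall == m.f1 == 1.0
            assert m.fp == m.fn == 0

    def test_base_level_set_arithmetic(self):
        pred = AnnotationSet.from_transcripts([tx("p", "gp", "chr1", "+", (0, 100))])
        ref = AnnotationSet.from_transcripts([tx("r", "gr", "chr1", "+", (50, 150))])
        base = evaluate(pred, ref)[0]
        assert (base.tp, base.fp, base.fn) == (50, 50, 50)
        assert base.precision == base.recall == 0.5

    def test_levels_in_canonical_order(self):
        ann = random_annotation(random.Random(3), n_genes=5)
        assert [m.level for m in evaluate(ann, ann)] == list(LEVELS)

    def test_matches_brute_force_oracle(self):
        rng = random.Random(29)
        for _ in range(8):
            ref = random_annotation(rng, n_genes=rng.randint(5, 15), region=60_000)
            pred = perturbed_copy(rng, ref)
            got = evaluate(pred, ref)
            expect = evaluate_oracle(pred, ref)
            for m in got:
                mp, pt, mr, rt = expect[m.level]
                assert (m.tp, m.fp, m.fn) == (mp, pt - mp, rt - mr), m.level
                assert m.precision == pytest.approx(mp / pt if pt else 0.0)
                assert m.recall == pytest.approx(mr / rt if rt else 0.0)

    def test_swapping_pred_and_ref_exchanges_precision_recall(self):
        rng = random.Random(31)
        ref = random_annotation(rng, n_genes=10)
        pred = perturbed_copy(rng, ref)
        fwd = evaluate(pred, ref)
        rev = evaluate(ref, pred)
        for a, b in zip(fwd, rev):
            assert a.precision == pytest.approx(b.recall)
            assert a.recall == pytest.approx(b.precision)

    def test_degradation_monotonicity(self):
        rng = random.Random(37)
        ref = random_annotation(rng, n_genes=10)
        pred_ts = list(ref.transcripts())
        full = evaluate(AnnotationSet.from_transcripts(pred_ts), ref)
        # deleting a predicted transcript never increases recall
        smaller = AnnotationSet.from_transcripts(pred_ts[:-3])
        for a, b in zip(evaluate(smaller, ref), full):
            assert a.recall <= b.recall + 1e-12
        # adding a spurious intergenic transcript never increases precision
        noisy = AnnotationSet.from_transcripts(
            pred_ts + [tx("junk", "junkg", "chr1", "+", (900_000, 900_700))]
        )
        for a, b in zip(evaluate(noisy, ref), full):
            assert a.precision <= b.precision + 1e-12

    def test_empty_prediction_is_degenerate_zero(self):
        ref = random_annotation(random.Random(5), n_genes=4)
        empty = AnnotationSet([])
        for m in evaluate(empty, ref):
            assert m.precision == 0.0 and m.f1 == 0.0
            assert m.degenerate


class TestExN50:
    def test_dominant_transcript_prefix(self):
        recs = [
            QuantRecord("a", 1000, 90.0),
            QuantRecord("b", 500, 9.0),
            QuantRecord("c", 100, 1.0),
        ]
        res = exn50(recs, 0.9)
        assert res.exn50 == 1000 and res.n_transcripts == 1

    def test_equal_expression_quartet(self):
        recs = [
            QuantRecord(n, L, 25.0)
            for n, L in zip("abcd", (100, 200, 300, 400))
        ]
        res = exn50(recs, 0.9)
        assert res.exn50 == 300 and res.n_transcripts == 4

    def test_single_transcript(self):
        assert exn50([QuantRecord("a", 777, 5.0)], 0.9).exn50 == 777

    def test_all_zero_tpm_rejected(self):
        with pytest.raises(ValueError):
            exn50([QuantRecord("a", 100, 0.0)], 0.9)

    def test_fraction_one_is_plain_n50(self):
        rng = random.Random(19)
        for _ in range(50):
            recs = [
                QuantRecord(f"t{i}", rng.randint(100, 5_000),
                            float(rng.randint(1, 50)))
                for i in range(rng.randint(1, 25))
            ]
            lengths = sorted((r.length for r in recs), reverse=True)
            half = sum(lengths) / 2
            acc = 0
            for L in lengths:
                acc += L
                if acc >= half:
                    break
            assert exn50(recs, 1.0).exn50 == L

    def test_matches_brute_force_on_random_tables(self):
        rng = random.Random(43)
        for _ in range(300):
            recs = [
                QuantRecord(
                    f"t{i}", rng.randint(100, 3_000),
                    round(rng.random() * rng.choice((0, 1, 10)), 3),
                )
                for i in range(rng.randint(1, 30))
            ]
            if sum(r.tpm for r in recs) == 0:
                continue
            frac = rng.choice((0.5, 0.9, 1.0))
            res = exn50(recs, frac)
            ex, n = exn50_oracle(recs, frac)
            assert (res.exn50, res.n_transcripts) == (ex, n)
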