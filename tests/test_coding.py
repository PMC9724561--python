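"""ORF prediction, translation, hexamer model and the 3-way classifier."""
import math
import random

import pytest

from annotrec.coding import (
    HexamerModel, ALL_HEXAMERS, TranslationError, classify_novel,
    coding_score, dinucleotide_shuffle, find_orfs, train_hexamer, translate,
)
from annotrec.simulate import CodonBias, classification_corpus, random_coding_sequence
from conftest import orf_oracle

ZERO_MODEL = HexamerModel({h: 0.0 for h in ALL_HEXAMERS})


class TestTranslate:
    def test_standard_code(self):
        assert translate("ATGAAA") == "MK"

    def test_trailing_stop_dropped(self):
        assert translate("ATGTGA") == "M"

    def test_internal_stop_rejected(self):
        with pytest.raises(TranslationError):
            translate("ATGTGAAAA")

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(TranslationError):
            translate("ATGAA")


class TestFindOrfs:
    def test_simple_complete_orf(self):
        (orf,) = find_orfs("ATGAAATAG", 1)
        assert orf.protein == "MK" and orf.complete3

    def test_no_start_codon(self):
        assert find_orfs("TTTTTTTTT", 1) == []

    def test_longest_orf_first(self):
        orfs = find_orfs("ATGTAAATGAAAAAATAG", 1)
        assert orfs[0].protein == "MKK"

    def test_three_prime_partial(self):
        (orf,) = find_orfs("ATGAAAAA", 1)
        assert orf.protein == "MK" and not orf.complete3

    def test_shared_stop_keeps_five_prime_most_atg(self):
        # two in-frame ATGs before one stop: a single ORF is reported
        orfs = find_orfs("ATGAAAATGAAATAA", 1)
        assert len([o for o in orfs if o.frame == 0]) == 1
        assert orfs[0].protein == "MKMK"

    def test_matches_brute_force_enumeration(self):
        rng = random.Random(41)
        for _ in range(300):
            seq = "".join(
                rng.choices("ACGTN", weights=(10, 10, 10, 10, 1),
                            k=rng.randint(0, 120))
            )
            got = [
                (o.frame, o.start, o.end, o.protein, o.complete3)
                for o in find_orfs(seq, 1)
            ]
            assert got == orf_oracle(seq, 1)


class TestHexamerModel:
    def test_identical_corpora_score_zero(self):
        seqs = ["ATGGCCATTGTAATGGGCCGC", "TTGACCGGTACCAAGGTCCA"]
        model = train_hexamer(seqs, seqs)
        assert all(v == 0.0 for v in model.table.values())

    def test_coding_only_hexamer_scores_positive(self):
        model = train_hexamer(["ATGGCC" * 30], ["TTTTTT" * 30])
        assert model.score("ATGGCC") > 0
        assert model.score("TTTTTT") < 0

    def test_too_short_training_sequences_rejected(self):
        with pytest.raises(ValueError):
            train_hexamer(["ACGTA"], ["ACGTA"])

    def test_planted_transition_bias_recovered_in_sign(self):
        """In-frame dicodon hexamers planted by the generator score
        positive for most up-weighted transitions."""
        rng = random.Random(8)
        bias = CodonBias(rng, 1.0)
        train = [random_coding_sequence(rng, bias, 300) for _ in range(400)]
        model = train_hexamer(train, None, seed=8)
        # up-weighted transitions are those the chain actually prefers
        counts = {}
        for seq in train[:200]:
            body = seq[3:-3]
            for i in range(0, len(body) - 5, 3):
                counts[body[i : i + 6]] = counts.get(body[i : i + 6], 0) + 1
        frequent = sorted(counts, key=counts.get, reverse=True)[:100]
        agree = sum(model.score(h) > 0 for h in frequent)
        assert agree / len(frequent) >= 0.95

    def test_dinucleotide_shuffle_preserves_composition(self):
        rng = random.Random(3)
        for _ in range(30):
            seq = "".join(rng.choices("ACGT", k=rng.randint(10, 300)))
            shuf = dinucleotide_shuffle(seq, rng)
            assert sorted(shuf) == sorted(seq)
            pairs = lambda s: sorted(s[i : i + 2] for i in range(len(s) - 1))
            assert pairs(shuf) == pairs(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]


class TestCodingScore:
    def test_zero_model_scores_zero(self):
        assert coding_score("ATGAAACCCGGGTTTTAG", ZERO_MODEL) == 0.0

    def test_short_sequence_scores_zero_with_warning(self, caplog):
        assert coding_score("ACG", ZERO_MODEL) == 0.0

    def test_coding_beats_own_shuffle(self):
        rng = random.Random(1)
        bias = CodonBias(rng, 0.3)
        train = [random_coding_sequence(rng, bias, 250) for _ in range(400)]
        model = train_hexamer(train, None, seed=1)
        wins = 0
        n = 200
        for _ in range(n):
            seq = random_coding_sequence(rng, bias, rng.randint(150, 300))
            # scored as the classifier scores: in frame across a
            # qualifying ORF, whole sequence otherwise
            if coding_score(seq, model, 100) > coding_score(
                dinucleotide_shuffle(seq, rng), model, 100
            ):
                wins += 1
        assert wins / n >= 0.9


class TestClassifyNovel:
    def test_partition_and_forced_labels(self):
        rng = random.Random(2)
        bias = CodonBias(rng, 0.3)
        mrna = random_coding_sequence(rng, bias, 300)  # 301-aa ORF
        junk = "TTTCTTCTTTTCCTTTCT" * 30  # no ATG at all
        classes, proteins = classify_novel(
            {"m": mrna, "j": junk}, ZERO_MODEL, None,
            min_aa=100, score_threshold=0.0,
        )
        labels = {c.transcript_id: c.label for c in classes}
        # zero model scores 0 >= threshold: ORF decides
        assert labels["m"] == "coding" and "m" in proteins
        assert labels["j"] == "lncRNA" or labels["j"] == "other"
        assert len(classes) == 2

    def test_boundary_thresholds(self):
        seqs = {"a": "ATG" + "AAA" * 200 + "TAG", "b": "TTT" * 100}
        classes, _ = classify_novel(
            seqs, ZERO_MODEL, None, min_aa=100, score_threshold=-math.inf
        )
        assert all(c.label != "lncRNA" for c in classes)
        classes, _ = classify_novel(
            seqs, ZERO_MODEL, None, min_aa=math.inf, score_threshold=0.0
        )
        assert all(c.label != "coding" for c in classes)

    def test_homology_rescues_low_score_orf(self):
        from annotrec.io import BlastHit

        low = HexamerModel({h: -1.0 for h in ALL_HEXAMERS})
        seq = {"t1": "ATG" + "AAA" * 150 + "TAG"}
        hit = BlastHit("t1", "s", 99.0, 150, 1, 0, 1, 150, 1, 150, 1e-40, 500.0)
        classes, _ = classify_novel(seq, low, [hit], min_aa=100)
        assert classes[0].label == "coding" and classes[0].has_homology
        # without the hit the same transcript is 'other'
        classes, _ = classify_novel(seq, low, None, min_aa=100)
        assert classes[0].label == "other"

    def test_label_recovery_on_planted_corpus(self):
        train, seqs, truth = classification_corpus(
            seed=1, n_coding=50, n_noncoding=50, n_train=400
        )
        model = train_hexamer(list(train.values()), None, seed=1)
        classes, _ = classify_novel(seqs, model)
        acc = sum(c.label == truth[c.transcript_id] for c in classes) / len(classes)
        assert acc >= 0.9
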