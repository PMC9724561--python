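"""Best-hit selection and paralog / homolog / isoform assignment."""
import random

import pytest

from annotrec.core import GenomicInterval
from annotrec.homology import (
    HomologyParams, assign_homology, best_hit_per_query, identity_histogram,
)
from annotrec.io import BlastHit


def hit(q, s, pident=95.0, evalue=1e-50, bitscore=500.0):
    return BlastHit(q, s, pident, 300, 10, 0, 1, 300, 1, 300, evalue, bitscore)


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestBestHit:
    def test_lowest_evalue_wins(self):
        hits = [hit("q1", "a", evalue=1e-10), hit("q1", "b", evalue=1e-50)]
        assert best_hit_per_query(hits)["q1"].sseqid == "b"

    def test_single_hit_is_itself(self):
        h = hit("q1", "a")
        assert best_hit_per_query([h])["q1"] is h

    def test_tie_broken_by_bitscore_then_order(self):
        hits = [
            hit("q1", "a", evalue=1e-20, bitscore=100.0),
            hit("q1", "b", evalue=1e-20, bitscore=300.0),
            hit("q1", "c", evalue=1e-20, bitscore=300.0),
        ]
        assert best_hit_per_query(hits)["q1"].sseqid == "b"

    def test_matches_brute_force_argmin(self):
        rng = random.Random(13)
        for _ in range(50):
            hits = [
                hit(
                    f"q{rng.randint(1, 5)}", f"s{i}",
                    evalue=rng.choice([1e-5, 1e-20, 1e-50]),
                    bitscore=float(rng.randint(50, 500)),
                )
                for i in range(rng.randint(1, 30))
            ]
            best = best_hit_per_query(hits)
            for q in {h.qseqid for h in hits}:
                pool = [h for h in hits if h.qseqid == q]
                expect = min(
                    range(len(pool)),
                    key=lambda i: (pool[i].evalue, -pool[i].bitscore, i),
                )
                assert best[q] is pool[expect]


class TestAssignHomology:
    PARAMS = HomologyParams()

    def test_paralog_within_window(self):
        calls, dropped = assign_homology(
            {"q": hit("q", "s")},
            {"q": iv("chr1", 100_000, 110_000)},
            {"s": iv("chr1", 350_000, 360_000)},
            self.PARAMS,
        )
        (c,) = calls
        assert c.call == "paralog" and c.gap_bp == 240_000
        assert not dropped

    def test_different_chromosome_is_homolog(self):
        (c,), _ = assign_homology(
            {"q": hit("q", "s")},
            {"q": iv("chr1", 0, 10_000)},
            {"s": iv("chr2", 0, 10_000)},
            self.PARAMS,
        )
        assert c.call == "homolog_missing_gene" and c.gap_bp == -1

    def test_beyond_window_is_homolog(self):
        (c,), _ = assign_homology(
            {"q": hit("q", "s")},
            {"q": iv("chr1", 0, 10_000)},
            {"s": iv("chr1", 511_000, 520_000)},
            self.PARAMS,
        )
        assert c.call == "homolog_missing_gene"

    def test_overlap_is_missing_gene_isoform(self):
        (c,), _ = assign_homology(
            {"q": hit("q", "s")},
            {"q": iv("chr1", 100_000, 110_000)},
            {"s": iv("chr1", 105_000, 140_000)},
            self.PARAMS,
        )
        assert c.call == "missing_gene_isoform" and c.gap_bp == 0

    def test_identity_band_filter(self):
        calls, dropped = assign_homology(
            {"q": hit("q", "s", pident=85.0)},
            {"q": iv("chr1", 0, 1_000)},
            {"s": iv("chr1", 5_000, 6_000)},
            self.PARAMS,
        )
        assert not calls
        assert dropped[0].reason == "identity"

    def test_unplaced_subject_flagged_homolog(self):
        (c,), _ = assign_homology(
            {"q": hit("q", "s")},
            {"q": iv("chr1", 0, 1_000)},
            {"s": None},
            self.PARAMS,
        )
        assert c.call == "homolog_missing_gene" and c.subject_locus is None

    def test_query_without_locus_is_an_error(self):
        with pytest.raises(KeyError):
            assign_homology({"q": hit("q", "s")}, {}, {"s": None}, self.PARAMS)

    def test_partition_calls_plus_dropped(self):
        rng = random.Random(4)
        best = {}
        qloci, sloci = {}, {}
        for i in range(40):
            q, s = f"q{i}", f"s{i}"
            best[q] = hit(q, s, pident=rng.uniform(70, 100))
            qloci[q] = iv("chr1", i * 20_000, i * 20_000 + 5_000)
            sloci[s] = iv(rng.choice(("chr1", "chr2")),
                          rng.randint(0, 900_000), rng.randint(900_001, 950_000))
        calls, dropped = assign_homology(best, qloci, sloci, self.PARAMS)
        assert len(calls) + len(dropped) == len(best)

    def test_widening_window_never_demotes_paralog(self):
        narrow = HomologyParams(locus_window=200_000)
        wide = HomologyParams(locus_window=800_000)
        for gap in (50_000, 190_000, 210_000, 790_000):
            loci = (
                {"q": iv("chr1", 0, 10_000)},
                {"s": iv("chr1", 10_000 + gap, 20_000 + gap)},
            )
            (cn,), _ = assign_homology({"q": hit("q", "s")}, *loci, narrow)
            (cw,), _ = assign_homology({"q": hit("q", "s")}, *loci, wide)
            if cn.call == "paralog":
                assert cw.call == "paralog"


class TestIdentityHistogram:
    def test_bin_structure_and_threshold_subset(self):
        hits = [hit(f"q{i}", "s", pident=p)
                for i, p in enumerate([50, 85, 91, 95, 99.5, 100])]
        counts = identity_histogram(hits, bin_width=5.0)
        assert sum(counts.values()) == len(hits)
        over_90 = sum(v for k, v in counts.items()
                      if float(k.split("-")[0]) >= 90)
        assert over_90 == sum(h.pident >= 90 for h in hits)
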