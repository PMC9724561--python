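"""ORF prediction and coding-potential classification of novel transcripts.

The classifier routes novel transcripts into ``coding``, ``lncRNA`` or
``other``.  Coding potential is a transparent hexamer log-likelihood
ratio: a model trained on known coding sequences versus noncoding
sequences (or dinucleotide-preserving shuffles of the coding set when no
noncoding corpus is supplied) scores each transcript's best open reading
frame.  This plays the role that a trained lncRNA classifier plays in a
full annotation pipeline, with the same inputs and training interface,
but with an auditable decision rule:

* ``lncRNA``  - coding score below the threshold and no ORF of at least
  ``min_aa`` amino acids;
* ``coding``  - an ORF of at least ``min_aa`` amino acids and (score at or
  above the threshold, or a qualifying protein-homology hit);
* ``other``   - everything else (short ORF with high score, long ORF with
  low score and no homology, ...).

Defaults: ``min_aa=100`` (the common minimum-protein-length convention),
``score_threshold=0`` (log-ratio sign), ``pseudocount=1``.
"""
from __future__ import annotations

import itertools
import logging
import math
import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .io import BlastHit

log = logging.getLogger("annotrec")

DEFAULT_MIN_AA = 100
DEFAULT_SCORE_THRESHOLD = 0.0
DEFAULT_PSEUDOCOUNT = 1.0
EVALUE_MAX = 1e-5
QCOV_MIN = 10.0

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class TranslationError(ValueError):
    """CDS not translatable under the standard code."""


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    A single trailing stop codon is dropped; an internal stop or a length
    not divisible by 3 raises :class:`TranslationError`.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise TranslationError("internal stop codon")
    return protein


@dataclass(frozen=True)
class ORF:
    """An ATG-initiated open reading frame in transcript coordinates.

    ``start``/``end`` are 0-based half-open on the transcript and include
    the stop codon when one terminates the frame (``complete3``).
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    protein: str
    complete5: bool = True
    complete3: bool = True

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span not a codon multiple")

    @property
    def aa_length(self) -> int:
        return len(self.protein)


def find_orfs(seq: str, min_aa: int, transcript_id: str = "") -> list[ORF]:
    """All ATG-initiated ORFs in the three forward frames.

    Each ORF runs from an ATG to the first in-frame stop (included in the
    span) or to the frame's end when no stop occurs (3'-partial).  ORFs
    sharing a stop keep only the longest, i.e. the 5'-most ATG.  Results
    are sorted by protein length descending, ties by start ascending, and
    filtered to proteins of at least ``min_aa`` residues.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = seq.upper()
    orfs: list[ORF] = []
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                orfs.append(_make_orf(seq, transcript_id, frame, start, pos + 3, True))
                start = None
        if start is not None:  # ran off the end without a stop: 3'-partial
            end = start + 3 * ((len(seq) - start) // 3)
            if end > start:
                orfs.append(_make_orf(seq, transcript_id, frame, start, end, False))
    orfs = [o for o in orfs if o.aa_length >= min_aa]
    orfs.sort(key=lambda o: (-o.aa_length, o.start))
    return orfs


def _make_orf(
    seq: str, tid: str, frame: int, start: int, end: int, complete3: bool
) -> ORF:
    cds = seq[start : end - 3] if complete3 else seq[start:end]
    return ORF(
        transcript_id=tid,
        frame=frame,
        start=start,
        end=end,
        protein=str(Seq(cds).translate()),
        complete5=True,
        complete3=complete3,
    )


# ---------------------------------------------------------------------------
# Hexamer model
# ---------------------------------------------------------------------------

ALL_HEXAMERS = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=6)
)


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide counts.

    Altschul-Erickson style: build the multigraph of observed
    dinucleotide transitions and sample a random Eulerian walk from the
    original start nucleotide.
    """
    seq = seq.upper()
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    # Random last-edge choice per vertex must keep the walk completable:
    # fix a spanning arborescence to the terminal vertex, place those
    # edges last, shuffle the rest (the standard doublet-shuffle trick).
    last = seq[-1]
    vertices = sorted(edges)
    last_edge: dict[str, str] = {}
    for v in vertices:
        if v == last:
            continue
        # walk from v to `last` through random successors to pick a
        # reachable final edge
        for _ in range(100):
            u, path = v, []
            seen = set()
            while u != last and u not in seen:
                seen.add(u)
                nxt = rng.choice(edges[u])
                path.append((u, nxt))
                u = nxt
            if u == last:
                for a, b in path:
                    last_edge.setdefault(a, b)
                if v in last_edge:
                    break
        if v not in last_edge:  # no path: sequence not shuffleable, keep as is
            return seq
    shuffled_edges: dict[str, list[str]] = {}
    for v in vertices:
        bag = list(edges[v])
        if v in last_edge:
            bag.remove(last_edge[v])
        rng.shuffle(bag)
        if v in last_edge:
            bag.append(last_edge[v])
        shuffled_edges[v] = bag
    out = [seq[0]]
    counters = {v: 0 for v in vertices}
    u = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[u][counters[u]]
        counters[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


@dataclass
class HexamerModel:
    """Per-hexamer log2(coding frequency / noncoding frequency) table.

    Pseudocount smoothing guarantees every one of the 4096 DNA hexamers
    has a finite score.
    """

    table: dict[str, float]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        missing = [h for h in ALL_HEXAMERS if h not in self.table]
        if missing:
            raise ValueError(f"{len(missing)} hexamers missing from model")

    def score(self, hexamer: str) -> float:
        return self.table.get(hexamer.upper(), 0.0)


def _hexamer_counts(seqs: Iterable[str]) -> dict[str, int]:
    counts = {h: 0 for h in ALL_HEXAMERS}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - 5):
            hx = seq[i : i + 6]
            if hx in counts:  # skip windows containing N
                counts[hx] += 1
    return counts


def train_hexamer(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
) -> HexamerModel:
    """Train the hexamer log-ratio model.

    Hexamers are counted in sliding windows of step 1.  When no noncoding
    corpus is given, one is synthesised by a seeded dinucleotide-preserving
    shuffle of each coding sequence, which keeps base and dinucleotide
    composition while destroying codon structure.
    """
    if not coding_seqs:
        raise ValueError("need at least one coding sequence")
    if noncoding_seqs is None or len(noncoding_seqs) == 0:
        rng = random.Random(seed)
        noncoding_seqs = [dinucleotide_shuffle(s, rng) for s in coding_seqs]
    cod = _hexamer_counts(coding_seqs)
    non = _hexamer_counts(noncoding_seqs)
    if sum(cod.values()) == 0 or sum(non.values()) == 0:
        raise ValueError("all training sequences shorter than 6 nt")
    cod_total = sum(cod.values()) + pseudocount * len(ALL_HEXAMERS)
    non_total = sum(non.values()) + pseudocount * len(ALL_HEXAMERS)
    table = {
        h: math.log2(
            ((cod[h] + pseudocount) / cod_total)
            / ((non[h] + pseudocount) / non_total)
        )
        for h in ALL_HEXAMERS
    }
    return HexamerModel(table, pseudocount)


def coding_score(seq: str, model: HexamerModel, min_aa: int = 1) -> float:
    """Mean hexamer log-ratio of ``seq`` under ``model``.

    When an ORF of at least ``min_aa`` residues exists, hexamers are read
    in frame (step 3) across the best such ORF, so the score measures
    codon-structure likelihood where the classifier will look for a
    protein.  Without a qualifying ORF the whole sequence is scanned at
    step 1.  Sequences shorter than one hexamer score 0 with a warning.
    """
    seq = seq.upper()
    orfs = find_orfs(seq, min_aa=min_aa)
    if orfs:
        region, step = seq[orfs[0].start : orfs[0].end], 3
    else:
        region, step = seq, 1
    if len(region) < 6:
        log.warning("sequence shorter than 6 nt; coding score 0")
        return 0.0
    scores = [
        model.score(region[i : i + 6])
        for i in range(0, len(region) - 5, step)
        if set(region[i : i + 6]) <= set("ACGT")
    ]
    return float(sum(scores) / len(scores)) if scores else 0.0


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptClass:
    transcript_id: str
    label: str  # coding | lncRNA | other
    coding_score: float
    orf_coverage: float  # best-ORF length / transcript length
    has_homology: bool


def filter_homology_hits(
    hits: Iterable[BlastHit],
    evalue_max: float = EVALUE_MAX,
    qcov_min: float = QCOV_MIN,
) -> set[str]:
    """Query ids with a qualifying hit (evalue and, when present, qcov)."""
    keep = set()
    for h in hits:
        if h.evalue > evalue_max:
            continue
        if h.qcov is not None and h.qcov < qcov_min:
            continue
        keep.add(h.qseqid)
    return keep


def classify_novel(
    sequences: Mapping[str, str],
    model: HexamerModel,
    homology_hits: Iterable[BlastHit] | None = None,
    min_aa: int = DEFAULT_MIN_AA,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    evalue_max: float = EVALUE_MAX,
    qcov_min: float = QCOV_MIN,
    lncrna_first: bool = True,
) -> tuple[list[TranscriptClass], dict[str, str]]:
    """Route novel transcripts into coding / lncRNA / other.

    ``sequences`` maps transcript id to spliced sequence.  Returns the
    per-transcript classifications (input order) and the deduced proteins
    of the coding transcripts.  The two label tests are mutually
    exclusive by construction; ``lncrna_first`` selects which is tried
    first for the degenerate configurations where both could fire (e.g.
    ``min_aa`` or thresholds moved to pathological values).
    """
    with_hom = (
        filter_homology_hits(homology_hits, evalue_max, qcov_min)
        if homology_hits is not None
        else set()
    )
    classes: list[TranscriptClass] = []
    proteins: dict[str, str] = {}
    for tid, seq in sequences.items():
        score = coding_score(seq, model, min_aa=min_aa)
        orfs = find_orfs(seq, min_aa=1, transcript_id=tid)
        best = orfs[0] if orfs else None
        coverage = (best.end - best.start) / len(seq) if best and seq else 0.0
        has_hom = tid in with_hom
        long_orf = best is not None and best.aa_length >= min_aa
        is_lnc = score < score_threshold and not long_orf
        is_coding = long_orf and (score >= score_threshold or has_hom)
        if lncrna_first:
            label = "lncRNA" if is_lnc else ("coding" if is_coding else "other")
        else:
            label = "coding" if is_coding else ("lncRNA" if is_lnc else "other")
        if label == "coding":
            proteins[tid] = best.protein
        classes.append(TranscriptClass(tid, label, score, coverage, has_hom))
    counts = {"coding": 0, "lncRNA": 0, "other": 0}
    for c in classes:
        counts[c.label] += 1
    log.info("classified %d transcripts: %s", len(classes), counts)
    return classes, proteins
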