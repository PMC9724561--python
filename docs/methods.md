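# Methods

This note documents the models and procedures `annotrec` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic test bed does and does not show
about real data.

## Coordinates and the domain model

All internal coordinates are 0-based half-open on a named chromosome with
strand `+`, `-` or `.`; GTF files (1-based inclusive) are converted once,
at the I/O boundary. A transcript is an ordered, disjoint exon chain on
one strand; its introns are the gaps between consecutive exons, and two
multi-exon transcripts match "by chain" when their ordered intron
coordinate lists are identical. Exons that overlap or abut within one
input transcript are merged with a warning rather than rejected, because
real assembler GTFs contain such records. Transcripts with strand `.`
participate in unstranded overlap queries only and are excluded from all
strand-aware metrics (their count is logged) — silently assigning them a
strand would corrupt antisense calls.

## Reconciliation

Assembled transcripts are classified against the reference with five
ordered rules (exact → isoform → novel_intronic → novel_antisense →
novel_intergenic); the first that fires wins. The published pipelines in
this space perform this step with BEDtools/gffread heuristics whose exact
rules are not printed; the five-class scheme here, modelled on the
gffcompare class codes `=`, `j`, `i`, `x`, `u`, is this package's
normative, testable definition.

Parameters:

- **single-exon exact threshold** — 80% reciprocal span overlap
  (fraction, default 0.8, configurable). Mirrors the usual single-exon
  matching convention; intron chains are undefined for mono-exonic
  transcripts.
- **isoform tie-break** — greatest exonic overlap in bp, ties to the
  lexicographically smaller gene id. A transcript spanning two genes
  (read-through) is assigned to the single best-overlap gene and never
  split; the overlap is recorded so the ambiguity stays visible.

Gene symbols come from the `gene_name` GTF attribute when present, else
`gene_id`, matching reference-annotation dialects.

## ORF prediction and coding potential

`find_orfs` reports ATG-initiated ORFs in the three forward frames only
(assembled transcripts are stranded), each running to the first in-frame
stop (included in the span) or to the sequence end (3'-partial). ORFs
sharing a stop collapse to the 5'-most ATG. 5'-partial ORFs (stop-free
prefixes without an ATG) are not reported in this version.

Coding potential is a hexamer log-likelihood ratio: for each of the 4096
DNA hexamers, log2 of its frequency in a coding corpus over its frequency
in a noncoding corpus, with pseudocount smoothing (default 1) so every
score is finite. Training counts use sliding windows of step 1. When no
noncoding corpus is supplied, one is synthesised by a seeded
dinucleotide-preserving shuffle (Altschul–Erickson style Eulerian-walk
shuffle) of each coding sequence — the standard null that keeps base and
dinucleotide composition while destroying codon structure.

**Scoring** reads hexamers *in frame* (step 3) across the best ORF of at
least `min_aa` residues; a sequence with no qualifying ORF is scanned at
step 1 over its whole length. Rationale: the discriminative signal —
biological codon/dicodon usage, and the planted signal in the test bed —
is codon-phased. An unphased scan dilutes it threefold with out-of-frame
windows; reading in frame across the ORF is how hexamer features are
used in coding-potential tools generally.

The classifier routes each transcript with score *s*, threshold *t*
(default 0 = the log-ratio sign), and ORF cutoff `min_aa` (default 100
aa, the common minimum-protein convention):

- `lncRNA` when *s* < *t* and no qualifying ORF;
- `coding` when a qualifying ORF exists and (*s* ≥ *t* or a homology hit
  with e-value ≤ 1e-5 and, when the column is present, query coverage
  ≥ 10%);
- `other` otherwise.

The two label tests are mutually exclusive under any sane configuration;
a flag selects which is evaluated first for pathological settings. The
`other` bucket is deliberate: short-ORF/high-score and long-ORF/low-score
transcripts are real categories (small peptides, incomplete models,
repeat-derived fragments) and forcing them into coding/lncRNA would
fabricate certainty. This transparent rule replaces external
random-forest classifiers on purpose: same inputs, same outputs, same
training interface, but auditable and self-contained.

## lncRNA positional classification

The partner is the overlapping coding gene with the largest exonic
overlap, else the nearest coding gene within the window (default 100 kb),
ties to the smaller gene id; no partner → `orphan`. Genic lncRNAs are
`exonic` (≥ 1 bp exon–exon overlap), `containing` (lncRNA span strictly
contains the partner span, no exon overlap) or `intronic`. Intergenic
lncRNAs are `upstream`/`downstream` in the partner's frame of reference;
antisense + upstream = `divergent` (head-to-head), antisense + downstream
= `convergent` (tail-to-tail), sense = `same_strand`. Distance is the gap
between closest span ends (0 when touching; genic distance is 0 by
definition). Partner candidates are restricted to coding genes, which is
what the location/type pie charts in annotation studies describe.

The geometric invariant tested is the true mirror: reflecting all
coordinates about a fixed point *and* flipping all strands preserves
every (relation, direction, location, subtype, distance) tuple. A strand
flip alone is *not* a symmetry of the subtype system — it swaps
head-to-head and tail-to-tail — and is deliberately not asserted.

## Homology calls

Best hit per query = lowest e-value, ties by highest bitscore, then first
occurrence (the behaviour of running BLAST with one target and one HSP
per query). Hits outside the identity band (defaults 90–100%; prose
descriptions like "near 100%" are treated as the same band) or above the
e-value ceiling (1e-5) are dropped with a reason. Remaining hits are
classified in order: query locus overlaps subject locus →
`missing_gene_isoform`; same chromosome and gap < window (default
0.5 Mb) → `paralog`; otherwise (including unplaced subjects) →
`homolog_missing_gene`. "Within the same locus" is operationalised as the
gap between spans, excluding overlap, because the published distance
threshold does not state a measuring convention and gap-between-spans is
the unambiguous choice. Subject loci derive from the reference GTF
(protein/transcript id → gene span); a sidecar TSV can override or extend
them for proteins absent from the GTF, and an orthology table
(eggNOG-style) can be joined onto the output — a table join only, never
an execution.

## Six-level evaluation

Levels: base (strand-aware exonic-base set arithmetic, in bp), exon and
intron (unique exact coordinates), intron chain (ordered chain equality;
precision over predicted multi-exon transcripts, recall over reference
multi-exon transcripts), transcript (chain match, or 80% reciprocal
overlap for single-exon pairs), locus (transcripts clustered by
same-strand exonic overlap under transitive closure; a predicted locus
counts when any member has a transcript match, a reference locus when any
member is matched). Precision is TP/(TP+FP) and recall TP/(TP+FN); F1 is
their harmonic mean, 0 when both are 0. At the asymmetric levels `tp`
counts matched predicted items and `fn` unmatched reference items, so
precision is pred-side and recall ref-side; swapping prediction and
reference exchanges the two exactly. Terminal exon coordinates are
matched exactly — no fuzzy end tolerance — for determinism. Empty inputs
yield precision/recall 0 flagged as degenerate rather than an error.

ExN50: rank transcripts by TPM (ties: longer first, then id), take the
minimal prefix reaching the expression fraction (default 0.9) of total
TPM, and report the N50 of that prefix's lengths. With fraction 1 this is
the plain N50 of all expressed transcripts.

## The synthetic test bed

The generator emulates the statistical structure the pipeline assumes: a
reference of protein-coding genes; an assembly derived from it by
dropping transcripts, shifting exon boundaries, adding isoforms
(exon-skip), planting intergenic coding and noncoding transcripts,
antisense exonic overlaps and divergent upstream lncRNAs; 90–100%
identity paralog pairs at controlled genomic gaps; a quantification
table; and a complete truth table. All randomness flows from one seed and
equal seeds give byte-identical files.

Key constructions and the default study conditions:

- **Genome/genes** — 2 chromosomes × 1.5 Mb, 20 genes, 1–6 exons of
  150–400 bp, introns 300–2000 bp, intergenic gaps 25–60 kb. Coding
  layouts are padded to a codon multiple comfortably above the 100-aa ORF
  cutoff.
- **Hexamer signal** — coding sequences are ATG + codons from a
  first-order Markov chain over the 61 sense codons with ±0.3 log-odds
  transition weights + stop. The bias sits in codon *transitions*
  (dicodons) deliberately: a marginal codon bias survives the
  dinucleotide-preserving shuffle that defines the noncoding class and
  would therefore not be a hexamer signal at all, whereas transition bias
  is exactly a hexamer contrast. Noncoding sequences are shuffles
  regenerated until they carry no qualifying ORF, so planted labels are
  well defined. Training corpus: 1000 sequences of 150–350 codons —
  the order of magnitude real classifiers train on (thousands of known
  mRNAs). Under these conditions coding-label recovery on a 100+100
  planted test set is ≈ 0.95.
- **Paralog pairs** — the query is itself a planted coding transcript;
  its translated protein is copied and mutated by substitutions only, so
  percent identity is analytic ((L−k)/L); the subject locus is placed at
  an exact requested gap (or overlapping, for the missing-gene-isoform
  case). The distance rule's ground truth is therefore known by
  construction on both sides of the 0.5 Mb boundary.
- **Expression** — TPM from normalised exponential draws (a heavy-tailed
  expression profile), 10⁶ total.

What the fixtures do **not** model: sequencing errors and read-level
artefacts (assembly is perturbed structurally, not resequenced),
alternative TSS/polyA variation, overlapping gene dense regions,
paralogous sequence similarity at the DNA level between reference genes,
indels in paralog proteins, multi-isoform reference genes, and noncoding
reference genes. Passing tests therefore demonstrate correctness of the
*rules* and recoverability of *planted* signal at realistic sizes — not
classifier performance on real chicken (or any) transcriptomes, where
coding/noncoding contrasts are stronger in some respects (real codon
usage) and messier in others (UTRs, incomplete models).

Problem sizes in the test suite and the acceptance script (20-gene
fixtures, 50-fixture oracle sweeps, 200-sequence classification sets,
1000-iteration enumeration checks) were chosen as the smallest sizes at
which every rule and boundary case is exercised and recovery statistics
are stable.

## Numerical and degenerate-input choices

- Pseudocount smoothing guarantees finite hexamer scores; identical
  corpora give an all-zero model; sequences shorter than one hexamer
  score 0 with a warning.
- `score_threshold = −∞` forces no lncRNA labels and `min_aa = ∞` no
  coding labels (boundary behaviour, tested).
- All tie-breaks (isoform gene, lncRNA partner, best hit, ExN50 ranking)
  are total orders, so every output is deterministic and re-runs are
  byte-identical.
- Placement of planted features uses rejection sampling over an occupancy
  map with a 500 bp margin; an unsatisfiable spec raises a placement
  error naming the counts rather than silently shrinking the request.
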