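# annotrec

Reference-guided reconciliation, classification and benchmarking of
assembled transcriptomes.

Hybrid RNA-seq workflows (short + long reads) assemble transcripts with
tools like StringTie and then face the downstream half of the problem:
which assembled transcripts correspond to genes already in the reference
annotation, which are novel, what the novel ones are (protein-coding,
long noncoding, or neither), and how good a predicted annotation is
against a trusted reference. `annotrec` is a library and CLI for exactly
that half. It is aimed at genome-annotation and transcriptomics groups
working on organisms whose reference annotations are still incomplete
(birds, fish, non-model mammals), where assembled RNA-seq routinely
reveals genes the reference lacks.

## What it computes

**Reconciliation.** Every assembled transcript is matched to the
reference and assigned one of five classes, modelled on the gffcompare
class codes `=`, `j`, `i`, `x`, `u`:

| class | rule |
|---|---|
| `exact` | identical ordered intron chain (multi-exon), or ≥ 80% reciprocal span overlap with a single-exon reference transcript, same strand |
| `isoform` | ≥ 1 bp same-strand exon–exon overlap; assigned to the reference gene with the largest exonic overlap |
| `novel_intronic` | contained in a same-strand reference intron, no exon overlap |
| `novel_antisense` | exon overlap only with opposite-strand reference exons |
| `novel_intergenic` | none of the above |

Known transcripts are labelled by the reference gene symbol; novel ones
keep their assembler (`STRG`) id.

**Coding classification.** Open reading frames are predicted (ATG to
first in-frame stop, three forward frames) and each transcript is scored
with a hexamer log-likelihood-ratio model trained on known coding
sequences versus noncoding sequences (dinucleotide-preserving shuffles by
default). With score *s*, threshold *t* (default 0), and ORF length
cutoff `min_aa` (default 100):

- `lncRNA` if *s* < *t* and no ORF ≥ `min_aa`;
- `coding` if ORF ≥ `min_aa` and (*s* ≥ *t* or a qualifying protein
  homology hit, e-value ≤ 1e-5, query coverage ≥ 10%);
- `other` otherwise.

**lncRNA geometry.** Each lncRNA is positioned against its partner coding
gene: genic (exonic / intronic / containing) or intergenic (upstream /
downstream), sense or antisense, with the intergenic antisense cases
split into *divergent* (head-to-head) and *convergent* (tail-to-tail);
partner search window 100 kb by default.

**Homology calls.** From tabular BLASTP output (best hit per query by
e-value), hits in the 90–100% identity band are classified: query locus
overlapping the subject locus → `missing_gene_isoform`; same chromosome
within 0.5 Mb → `paralog`; otherwise → `homolog_missing_gene`.

**Benchmarking.** A predicted GTF is compared to a reference at six
levels — covered bases, exon, intron, intron chain, transcript, locus —
with precision = TP/(TP+FP), recall = TP/(TP+FN) and their harmonic mean

F1 = 2·precision·recall / (precision + recall),

plus the Ex90N50 metric: the N50 length of the most highly expressed
transcripts jointly accounting for 90% of total TPM.

**Synthetic fixtures.** A seeded generator (`annotrec simulate`) builds a
toy genome, reference GTF, perturbed assembly GTF, training corpora,
quantification and protein-hit tables — with a complete truth table —
so every stage can be tested end to end without external data.

## Worked example

```
annotrec simulate --outdir fixtures --seed 1
annotrec annotate \
    --assembly fixtures/assembly.gtf --reference fixtures/reference.gtf \
    --genome fixtures/genome.fa \
    --train-coding fixtures/train_coding.fa \
    --train-noncoding fixtures/train_noncoding.fa \
    --blast fixtures/blastp.tsv --subject-loci fixtures/subject_loci.tsv \
    --outdir out --seed 1
cat out/summary.tsv
```

prints

```
category	label	n_transcripts
known	coding	20
known	lncRNA	0
known	other	0
novel	coding	4
novel	lncRNA	3
novel	other	1
```

20 assembled transcripts matched reference genes (exact copies and the
planted boundary-shift/extra isoforms) and are coding, as expected since
the fixture's reference genes are all protein-coding. Of the 8 novel
transcripts, 4 are coding (2 planted intergenic mRNAs and the 2
paralog-pair queries), 3 are lncRNAs (2 planted intergenic noncoding
transcripts and the planted divergent lncRNA), and 1 — the planted
antisense transcript, whose sequence is the reverse complement of a
coding exon — passes neither test.
`out/reconciliation.tsv` lists the per-transcript match class,
`out/homology.tsv` the paralog calls, and

```
annotrec benchmark --pred fixtures/assembly.gtf --ref fixtures/reference.gtf --out metrics.tsv
annotrec exn50 --quant fixtures/quant.sf
```

give the six-level precision/recall/F1 table of the perturbed assembly
and its Ex90N50 (`Ex90N50  1073  n_transcripts  15` on this fixture).

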