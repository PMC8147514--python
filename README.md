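# isdetect

Detection of known, distant and **putative novel insertion-sequence (IS)
elements** in assembled prokaryotic contigs.

IS elements are the smallest autonomous mobile elements in bacteria and
archaea (~0.7–3 kb): a transposase ORF flanked by terminal inverted
repeats, creating a direct repeat on insertion. Annotation tools that
match whole elements or whole transposases against a reference database
find close homologs only. `isdetect` instead seeds its search with
**profile HMMs of transposase catalytic domains** — the most conserved
part of the protein — which lets it pick up distant family members and
candidates for novel families while keeping false positives moderate. It
is aimed at microbial genomicists annotating mobile elements and at anyone
hunting for new IS families.

## Method

1. **Seeding.** Every contig is translated in all six frames (translation
   table 11, whole sequence, not just ORFs). Each family profile is run
   over each frame with a local Viterbi search; domain hits with bit score
   ≥ 0 (family pHMMs) or conditional E-value ≤ 0.001 (single-sequence
   outlier profiles) become *seeds* at their genomic codon span.
2. **Merging.** Same-model seeds on one strand within 700 bp fuse
   (catalytic domains tolerate internal insertions); overlapping seeds
   from different models fuse too.
3. **Extension.** Each seed plus flanks (1 600 bp for the ORF window,
   14 000 bp for the DNA window) is aligned against a reference set of
   known transposases (translated Smith–Waterman) and full IS elements
   (nucleotide Smith–Waterman, both strands). The best database hit that
   still contains the whole seed re-draws the boundaries — at *dna* level
   for a full-IS match, *orf* level for a transposase match, otherwise the
   hit stays at *domain* level.
4. **Filtering.** Hits scoring below their model's noise cutoff NC — the
   bit score of the highest-scoring false positive observed on a curated
   decoy proteome — are removed, as are hits shorter than 150 bp and
   duplicates covering the same region.
5. **Classification.** Each hit gets a similarity category per level
   (SeqID = identities / database-item length; DNA thresholds 50 %/70 %,
   ORF thresholds 25 %/45 % separate *improbable*, *inter*- and
   *intra*-family similarity) and, when a GenBank annotation is supplied,
   an annotation category (*IS-related*, *no-annotation*,
   *other-annotation*, with misannotated integrases rescued and
   pseudo/incomplete records ignored).

The package also implements the **merged-false-positive evaluation
framework**: hits overlapping a curated element by ≥ 100 bp collapse to
one TP per element; unmatched hits mapping to the same known IS element
merge into one mFP; each mFP is classed as eIS (high-evidence IS), pNov
(distant/putative novel IS) or nIS (improbable/not an IS), giving
Se = TP/(TP+FN), FDR = 100·FP/(TP+FP), teIS = TP+eIS,
pNovDR = 100·pNov/(TP+mFP) and nISDR = 100·nIS/(TP+mFP).

A deterministic synthetic-fixture generator (`isdetect.synth`) emulates
the whole study — domain families, reference databases, decoy proteomes,
genomes with planted elements, toy GenBank annotation — so everything is
testable offline.

## Worked example

`examples/02_detect_in_genome.py` plants four IS copies in a 60 kb
synthetic genome and runs the full pipeline:

```
planted 4 elements, reported 4 hits

   start      end  ±   level SeqID_dna SeqID_orf   GenBank class
   13848    14865  -  domain       0.0       0.0      IS-related
   26415    27108  +     dna     100.0     100.0      IS-related
   44003    44696  -     dna     100.0     100.0      IS-related
   49587    50280  +     dna     100.0     100.0      IS-related
```

Three hits were extended to exact full-element boundaries by the
reference database (level `dna`, SeqID 100 % of the database item's
length); one is reported at catalytic-domain level because a background
seed merged into it and no database alignment contained the whole merged
seed — it is still classified IS-related through the overlapping
transposase annotation. All four overlap their planted element by
≥ 100 bp, so evaluation scores Se = 1.00 with zero false positives.

The same flow is available from the shell:

```sh
isdetect make-fixtures --seed 3 --outdir fx/
isdetect run --input fx/genome.fasta --genbank fx/genome.gbk \
    --models fx/families.hmm --db-is fx/is_db.fasta \
    --db-orf fx/tpase_db.fasta --outdir out/
```

writing `out/hits.csv`, `out/hits.gff3` and `out/summary.txt`.

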