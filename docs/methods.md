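# Methods

## The detection model

`isdetect` treats an IS element as detectable through the most conserved
part of its transposase: the catalytic domain (typically the DDE core).
Each IS family (or subfamily with a distinct domain architecture) is
represented by a profile HMM over an alignment of its catalytic domains;
families too heterogeneous to align are represented by single outlier
sequences turned into single-sequence profiles. Searching six-frame
translations of the whole contig — rather than predicted ORFs — keeps
domains visible across frameshifts, pseudogenised copies and unannotated
regions.

### Profile model and search engine

A profile has match states 1..M with emission probabilities, insert
states with their own emissions, and delete states; transitions follow
the standard 7-transition node layout (M→M/I/D, I→M/I, D→M/D). The
search is a **local max-path (Viterbi) dynamic programme**: a path enters
the model at any match state, paying the uniform local-entry probability
2/(M(M+1)) once, and leaves from any match state free of charge. The bit
score of a path is the sum of emission log-odds against the model
background plus log2 transition probabilities plus the entry term.
Without the entry term every isolated well-matching residue would score
positively and a ≥ 0-bit report floor would be meaningless; with it, a
reported domain must accumulate roughly log2(M(M+1)/2) bits of real
signal. Multiple domains per target are defined by masking: report the
best span, forbid paths through it, repeat until the best remaining score
falls below the report floor. Because a masked span can never be crossed
(every consumed position must be emitted), the masked re-search
decomposes exactly into the two flanking segments, which the
implementation exploits by recursing on segments; the hit set is
identical to literal mask-and-rescan. Stop codons (`*`) and ambiguous
translations (`X`) are unemittable, so domains never span an in-frame
stop — merging across stops happens later at the seed level, in genomic
coordinates.

The engine reports max-path scores rather than Forward sums. This keeps
the whole scoring path exactly checkable against brute-force path
enumeration, and all of the pipeline's thresholds (the 0-bit floor, the
noise cutoffs, the E-value fit) are calibrated within the same engine, so
the choice is self-consistent. Forward/Backward posterior decoding and
glocal alignment are out of scope.

### Model building

From an aligned family, columns with **more than 50 %** residue
occupancy become match states. Match emissions are residue counts with a
Laplace pseudocount of 1; transitions are counted from each row's implied
M/I/D path with a pseudocount of 1 per transition type; the background is
uniform (1/20), matching the uniform-composition synthetic data.
Families must supply at least **10 sequences** so the model generalises
beyond its training set; single outlier sequences are admitted explicitly
(`min_train=1`) and then receive BLOSUM62-derived emission pseudocounts
(5 soft counts distributed as P(·|observed residue) with conditionals
p(b|a) ∝ 2^(s(a,b)/2)) so that conservative substitutions still score.

### Calibrations

*E-values.* Best scores of a profile on i.i.d. background sequences are
Gumbel-distributed; `calibrate_evalue` fits location/scale by maximum
likelihood on `n_random` (default 200) sequences of `len_random` (default
200) residues and stores λ = 1/scale, τ = location. E(s) =
Z·(1−exp(−exp(−λ(s−τ)))) with Z the number of translated frames searched
(6 per contig). The search-space convention for the "conditional"
E-value is not externally fixed; this contract is documented and used
consistently for the outlier-profile filter (E ≤ 0.001).

*Noise cutoff.* NC is the bit score of the highest-scoring hit (≥ 0)
when the profile is queried against a decoy proteome known to contain no
true family members, and 0.0 when no decoy scores at all (the filter then
degrades to the ≥ 0-bit floor). The synthetic decoy proteome defaults to
300 proteins of 300 aa (90 kaa): the calibration is only meaningful when
the decoy space is comparable to or larger than the translated search
space of a target genome, mirroring the proteome-scale curated decoy sets
used for real libraries.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `domT` | 0.0 bits | report floor for family-profile domain hits |
| `e_dom` | 0.001 | E-value cutoff for single-sequence outlier profiles |
| `d_merge` | 700 nt | max gap for same-model seed merging (domains with insertions/variable segments) |
| `context_orf` | 1 600 nt | flank around a seed for the transposase (ORF) window |
| `context_dna` | 14 000 nt | flank for the full-IS (DNA) window |
| `L_min_nt` | 150 nt (50 aa) | minimum reported hit length (strictly shorter is dropped) |
| `dup_overlap_frac` | 0.5 | overlap fraction of the shorter hit that defines a duplicate |

Merging details: same-model merging applies transitively (score = max,
E-value = min of the merged parts); already-fused multi-model seeds merge
further only on overlap, which makes merging idempotent. Cross-model
merges keep the maximum score, not the sum — scores from different models
are not additive — and the noise-cutoff check later uses the NC of the
model that contributed that maximum. Extension windows are clamped at
contig edges; sequences are treated as linear (origin-spanning elements
are out of scope). A database alignment only qualifies for extension if
its genomic span contains the entire seed; the best qualifying hit is
chosen by score, then identities, then aligned length, then database id —
a total order that makes every run reproducible. SeqID is
100·identities / (database item's full length) at each level, 0 when no
alignment qualifies.

Alignment scoring defaults mirror common practice (none are externally
fixed): protein BLOSUM62 with gap open 11 / extend 1, nucleotide +2/−3
with gap open 5 / extend 2, a gap of length k costing open + k·extend.
Both engines are exact Smith–Waterman (a linear-memory score pass
locating the optimal footprint, then a full traceback on the clipped
region for identities); there is no heuristic word seeding — reference
databases at desk scale are small enough for exact DP.

## Classification and evaluation choices

Similarity boundaries put equality at the low threshold (50 % DNA, 25 %
ORF) into *improbable* and equality at the high threshold (70 %/45 %)
into *inter*: the printed thresholds are strict on the low side and
inclusive on the high side, and equality at the low bound is assigned
conservatively. "Significant identity" in the integrase rescue rule
means non-improbable at either level. Keyword matching is
case-insensitive substring over product/note/function/gene/
mobile_element_type qualifiers, with whole-word matching for keywords of
≤ 4 characters (DDE, short family names) to avoid accidental substrings.
When a hit overlaps both an uninformative and an informative non-IS
record, the informative one wins (other-annotation): rule order is
IS-related > no-annotation > other-annotation, applied to the overlapping
feature set as a whole.

In the evaluation, the mFP adjacency bound is the matched database
element's length — fragments of one element lie within its footprint.
The discovery-rate denominator is TP+mFP when a curated reference exists
and mFP alone otherwise; this is the only reading consistent with the
published rate/count pairs (e.g. 22/1173 = 1.88 %, 50/1157 = 4.32 %).
teIS = TP + eIS always (one published row prints one less; the identity
is kept). pNov/nIS is reported as 0 when pNov = 0, and flagged undefined
when nIS = 0 with pNov > 0. A merged FP group is classified through its
best member (highest seed score, then longest, then leftmost).

## What the synthetic generator emulates — and what it does not

`FixtureSpec` defaults define the study conditions: 3 families × 12
members, 100-aa domains diverged by i.i.d. substitution at rate 0.15
(mean pairwise identity ≈ 72 %, i.e. intra-family similarity), a 200 kb
uniform-random genome with 6 planted full-length elements on random
strands, 20 bp terminal inverted repeats, 8 bp target-site duplications,
and the 300×300-aa decoy proteome. Planted transposases are
back-translated with uniformly random synonymous codons. The generator
does **not** model codon usage, GC skew, repeat-rich backgrounds,
phylogenetically structured families, nested or truncated elements, or
composite transposons — so a passing recovery test demonstrates the
pipeline's mechanics (seeding through evaluation) under clean conditions,
not performance on real genomes, where diverged copies, fragments and
annotation noise dominate the error budget.

## Problem sizes and numerics

The default end-to-end study (200 kb, ~400 kaa of translated frames,
three M=100 profiles) runs in well under a minute on one core; the
acceptance script and the test suite use these sizes. Scores use −1e30
as minus infinity to keep the DP max() NaN-free; probabilities written to
the HMMER3-dialect text format are rounded to 5 decimals and renormalised
on read. Ties in the alignment traceback prefer diagonal, then gap in
the database item, then gap in the query. Degenerate inputs (contigs
shorter than a codon, empty decoy sets, zero-variance calibration score
distributions) raise or warn explicitly rather than returning silent
defaults.

## Known limitations

Raw-read input, IR/DR boundary detection (boundaries come from database
hits, not repeat search), circular replicons, forward-score statistics
and heuristic search acceleration are all out of scope. The CSV column
the output format calls `level` stands in for an otherwise undefined
"accuracy" attribute of the output record; the column name is
configurable at the writer.
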