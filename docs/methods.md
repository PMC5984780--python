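# Methods

## Candidate selection

Raw reads carry a 3′ sequencing adaptor (default
`TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC`). Trimming locates the adaptor prefix
over an aligned span of at least 10 nt with at most one mismatch — an exact
10-mer seed is taken first, otherwise the leftmost minimum-mismatch
placement — and cuts at its start. Inserts outside 15–45 nt, inserts
containing N, and reads without an adaptor hit are discarded; identical
inserts are collapsed with summed copy counts. All downstream statistics
are copy-weighted.

Mapping is exact: no mismatches, no indels, no splicing. The mapper is a
sorted array of 15-mer integer codes over the genome with full-length
verification of every seed hit, queried on both strands. Each sequence
reports one *primary* placement — the lexicographically smallest
`(chrom, start, strand)` hit, with `+` before `-` — plus `n_hits`, the
total number of exact placements. The lexicographic rule replaces the
random tie-breaking of report-one-alignment aligners with a reproducible
choice while `n_hits` preserves the information needed for the
uniquely-mapped-read audit (`n_hits == 1`). Splice-junction mapping is not
reproduced; contaminant removal is sequence-level (below), which captures
junction-spanning ncRNA fragments without a spliced aligner, and the
simulator never emits junction-spanning piRNAs.

Contaminants are removed hierarchically — rRNA/tRNA, then known miRNA
precursors, then predicted miRNA precursors — by strand-insensitive
substring containment: a read is removed iff its sequence or reverse
complement occurs exactly within a blacklist sequence. A read matching
several blacklists is charged to the earliest step. Finally reads of
24–34 nt become piRNA candidates; the copy-weighted candidate total is the
piRPM denominator. The filter report reconciles exactly at every step
(removed + remaining = previous remaining).

## Signature statistics

- **Length spectrum**: piRPM per read length; sums to 10⁶ over the
  candidate window.
- **Positional composition**: copy-weighted base frequencies at positions
  1–15 (5′→3′), reported in the U/A/C/G display alphabet (U ≡ T).
  Enrichment divides by a background — the sample's overall base frequency
  by default, or uniform 0.25 (under which enrichment = 4 × frequency).
- **Overlap spectrum**: reads on opposite strands of one chromosome pair at
  overlap *d* when their 5′ ends satisfy `five_prime(minus) −
  five_prime(plus) = d − 1`. Pairing is computed per chromosome by
  5′-position hashing (O(n)); only primary placements contribute. The
  spectrum reports, for each d = 1..20, the piRPM of reads with ≥ 1 partner
  at exactly d — each read counts once per d however many partners it has.
- **Ping-pong z-score**: z of the d = 10 value against the mean/SD of the
  other overlap lengths. A flat spectrum reports 0; a nonzero peak over a
  zero-variance background reports ±∞ (the enrichment is unbounded, not
  absent).
- **10A composition**: the positional composition restricted to the d = 10
  pairable subset. An empty subset raises an explicit error rather than
  returning zeros, so "no ping-pong activity" is never silently conflated
  with "0% A".

## Genomic association

Categories follow the precedence TE > exon > intron > intergenic with
≥ 1 bp interval overlap; genic categories split by read-vs-gene strand
(sense preferred when a read overlaps genes on both strands). Introns are
gene spans minus exons, so single-exon genes contribute no intron space.
TE-family profiles attribute each TE-overlapping read to its
maximal-overlap TE copy (lexicographic family tie-break), with sense/
antisense orientation against the annotated TE strand; unstranded (`.`)
repeats count as `+` per RepeatMasker convention, and unlabelled repeats
fall under `unknown_family`. Category fractions partition the denominator
exactly, and the TE fraction equals the family-profile piRPM total / 10⁶.

## Cluster detection and quantification

Detection is a deterministic threshold detector standing in for
probabilistic cluster finders, whose published adaptations leave key
parameters unstated; a deterministic rule gives testable contracts. All
gates are configuration-exposed with these defaults: candidates are sorted
by 5′ position per chromosome and chained into runs wherever consecutive 5′
ends are ≤ `max_gap` = 5000 nt apart; a run is a cluster when its read span
is ≥ 1000 nt and it has ≥ 5 distinct sequences, ≥ 10 copies, ≥ 10 copies/kb
and a 1U fraction ≥ 0.5. Directionality: ≥ 90% of copies on one strand ⇒
mono-directional; otherwise, if some split point along the 5′-sorted reads
leaves ≤ 10% of copies outside two contiguous opposite-strand blocks ⇒
bi-directional (divergent arms); otherwise dual-strand (interleaved).

Per-sample clusters are merged across samples by ≥ 1 bp genomic overlap,
transitively and strand-agnostically (dual-strand clusters make stranded
merging ill-defined); merging is idempotent and order-invariant. Merged
boundaries are then extended to cover overlapping transcripts with
FPKM ≥ 1 in at least one RNA-seq dataset, iterating to a fixpoint so chains
of expressed transcripts are absorbed; boundaries only grow, and the
fixpoint generally differs from a single pass.

Expression is piRPKM = copies / (cluster kb × candidate millions). A read
belongs to a cluster iff its 5′ position lies in the half-open cluster
interval, giving boundary-straddling reads a unique owner; piRPKM is
invariant to uniform copy rescaling. Stage values aggregate samples by
arithmetic mean (EG averages the E11 and E14 gonad samples). A cluster is
stage-enriched (`<stage>-piRC`) when its top stage is ≥ 0.1 piRPKM and
≥ 1.5-fold above the second-highest stage; everything below 0.1 in all
stages is `not_expressed`; the rest — including exact top ties, which can
never satisfy the fold rule — is `shared`.

Sample embedding is classical (Torgerson) MDS on Euclidean distances of
log₁₀(piRPKM + 0.01) profiles, computed by eigendecomposition of the
double-centred squared-distance matrix; per-dimension eigenvalue fractions
report the variance explained. The closed form is used (rather than an
iterative stress minimiser) because it is exact for realisable
configurations. Synteny flags an anchor pair as conserved when every
species has ≥ 1 cluster wholly inside the open interval between its two
ordered anchor genes; straddling clusters do not count.

## piRNA-associated transcripts

A read associates with a transcript when it overlaps the transcript's
genomic span by ≥ 1 bp — introns included, since intragenic-TE piRNAs are
frequently intronic. Tables carry sense/antisense/total piRPM (orientation
vs transcript strand), the unique-mapper fraction, and the embedded-TE
fraction (copies overlapping a TE that intersects the transcript span).
Top targets are ranked by total piRPM (configurable to sense- or
antisense-only) with a floor of 70 piRPM and a cap of 500, ties broken by
transcript id. Differential association keeps transcripts whose
pseudocounted ratio exceeds 2-fold; the 0.5-piRPM pseudocount is symmetric
and scale-appropriate for the 70+ piRPM targets it is applied to, and makes
one-stage-only targets comparable. Biotype breakdowns tally targets per
annotated biotype, reporting missing annotations as `unannotated` rather
than dropping them.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
sequencing physics. A random genome (default 1 Mb over two chromosomes)
carries: per-family TE consensus sequences (default four CR1-like families,
12 copies each, 1.5 kb) written in as copies mutated at 10% divergence,
including four blocks of three consecutive copies that act as TE-dense
cluster hosts and single copies embedded in gene introns; gene models with
exon blocks, strands and biotypes (TE-host genes are `uncharacterized`;
snoRNA genes never host TEs); and rRNA/tRNA/miRNA loci whose recorded
sense sequences double as the contaminant blacklists, so contaminant
fragments drawn from them map exactly. The FPKM table contains both
expressed (≥ 1) and unexpressed transcripts. Feature placement is a
sequential cursor per chromosome, which keeps classes disjoint and raises a
sizing error when requests exceed capacity.

Reads are emitted in the DNA alphabet as exact (strand-adjusted) genome
substrings, so the no-mismatch mapping contract holds by construction.
Cluster emission per stage is `round(n_reads × stage_weights[stage])` —
deterministic counts with stochastic positions, lengths (normal, clipped to
24–34 nt) and strands. The 1U bias is imposed by sampling 5′ positions from
the pool whose genomic 5′ base is T (or non-T with probability
1 − `u1_prob`), not by editing reads, which would break exact mapping.
Ping-pong pairs use a complementarity identity: anchoring a plus-strand
read at a position x with `genome[x] == T` and `genome[x+9] == A` and its
minus-strand partner with 5′ end at x+9 gives *both* mates a 5′ U and an A
at position 10 as exact genome substrings — no genome patching is needed,
and a fully forced sample has a 10A frequency of exactly 1 in the d = 10
subset. Bidirectional clusters emit the minus arm left of the midpoint and
the plus arm right of it; dual-strand clusters interleave strands at
random.

Noise classes per sample: dispersed TE-derived piRNAs (default 8000,
75% antisense to the TE), rRNA/tRNA fragments (3000/1500, 24–34 nt so only
the blacklist — not the length filter — can remove them), known/predicted
mature miRNAs (1500/800, 18–23 nt, removed at their blacklist steps before
the length window is applied), and uniform genomic degradation reads of
24–34 nt that survive the whole cascade and stress the annotation and
cluster stages. Degradation reads are separability-guarded: any draw whose
sequence matches a planted piRNA, a blacklist, or an ncRNA locus interval
is redrawn, so truth classes are disjoint by sequence and filter
recall/precision are exactly computable. The default degradation depth is
100 reads/sample: uniform background at this density has mean spacing
(~10 kb) twice the cluster-chaining gap, so background alone neither forms
clusters (it also fails the 1U gate) nor welds planted clusters together.

The default study conditions are five samples (BC, PGC, E11G, E14G, AT;
E11G/E14G aggregate to the EG stage), ~200 k reads each (per-stage depths
are not dictated by the modelled experiment and are configurable), and
twelve planted clusters — four TE-dense, four genic, four intergenic, with
stage-weight profiles sliding from TE-dominant emission in BC to
intergenic-dominant emission in AT, u1_prob 0.85, ping-pong fraction 0.08
(0.2 for dual-strand clusters), seed 42.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: base-call errors and quality scores, PCR
duplication, ligation biases, spliced piRNA precursors, nested/fragmented
TE copies, genuine proTRAC probability models, and real genome composition
(GC structure, repeats beyond the planted families). Results on synthetic
data validate the *algorithms and their contracts*, not biological effect
sizes.

## Numerical and degenerate-input choices

- Empty samples (denominator 0) raise explicit errors wherever a piRPM or
  fraction would divide by zero; the empty d = 10 subset raises its own
  signal.
- Composition positions beyond a read's length are excluded from that
  position's denominator.
- All tie-breaks are lexicographic (primary placements, TE family
  attribution, target ranking), making every output order-deterministic;
  no unordered container reaches an output file.
- Transcript extension is monotone and bounded by chromosome spans; the
  50-iteration guard is unreachable on well-formed input.
- MDS eigenvalues are clipped at zero before taking square roots; variance
  fractions are over the positive eigenvalue mass.
- Test and acceptance problem sizes (e.g. 3000-read-per-cluster noiseless
  recovery fixtures, 20 k-read recovery samples) are chosen so sampling
  error sits well inside the asserted tolerances while the whole suite
  stays fast.

## Known limitations

- Exact-match mapping discards genuine piRNAs carrying SNVs or sequencing
  errors; on real data the candidate set is therefore conservative.
- Sequence-level contaminant removal can delete a true piRNA whose
  sequence happens to be contained in an ncRNA — the price of catching
  junction-spanning fragments without a spliced aligner.
- The run-chaining cluster detector welds loci closer than `max_gap` when
  dense background spans the gap; `max_gap` and the density gates are the
  controls.
- Stage aggregation by arithmetic mean treats member samples as equally
  deep; piRPM normalisation makes this reasonable but not exact for very
  unequal libraries.
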