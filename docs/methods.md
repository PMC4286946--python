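# Methods

This note documents the models, parameter choices and numerical conventions
behind pirnapipe, and what the synthetic-data generator does and does not
emulate.

## Read cleaning

A read is retained when, after 3′ adapter trimming, it contains no N, its
mean per-base Phred quality is ≥ `min_mean_quality` (default 13) and its
length lies in `[min_length, max_length]` (default 18–44 nt, the small-RNA
selection window).  Filter order is trim → quality → length so that
retention is decided by the insert, not by adapter bases.  The quality rule
is applied to the whole read ("mean" mode) because the upstream contract
filters reads, not bases; an "any_base" mode is available.

Adapter trimming is a best semi-global match of a read suffix against the
adapter prefix: the leftmost start with ≥ `min_adapter_overlap` (default 6)
overlapping bases and ≤ 10% mismatches in the overlap wins, and the read is
cut at that start.  Exact occurrences are found by substring search; the
mismatch-tolerant scan only runs when the exact paths fail.  The default
adapter is a 33-nt Illumina-style small-RNA 3′ adapter; real protocols vary,
so it is configurable everywhere.

## Mapping

The contract: a tag of length L (18–44 nt) maps at a locus if an ungapped
window of ≥ ⌈c·L⌉ consecutive tag bases (coverage c = 0.95) aligns with at
most ⌊(1−i)·w⌋ mismatches (identity i = 0.90, w the window length).  At
these lengths the contract admits at most 4 mismatches and 2 trimmed bases,
so gapped alignment would change nothing; the mapper is therefore an
exact-seed index over the genome plus ungapped window evaluation on each
candidate diagonal.  Per diagonal the longest qualifying window is reported
(leftmost trim on ties); identical windows proposed by adjacent diagonals
are deduplicated keeping the best identity.

Seeding is exhaustive over all tag offsets.  Seed length is a parameter with
an automatic default: on genomes < 200 kb, k = 6 — by the pigeonhole
principle every qualifying alignment of an 18–44-nt tag contains an exact
6-mer, so the search is provably complete, which is what the
oracle-equivalence tests exercise; on larger genomes, k = 12 — complete for
every alignment containing an exact 12-mer run, in particular for every
exact-substring placement, which is the regime the simulator produces
(reads are exact genome substrings; the quality model does not introduce
base-call errors).  k-mers are encoded base-5 with a sentinel digit padding
chromosome boundaries, so seeds can never match across chromosomes.

Tags mapping to more than `max_loci` (default 500) placements keep their
full locus count (used for multi-mapping weights) but a truncated locus
list, with an overflow flag.

## Annotation

Every (locus, feature) pair with ≥ 50% of the locus inside the feature is
collected; the tag receives the single highest-priority category over all
pairs: tRNA > rRNA > snRNA > snoRNA > scRNA > miRNA > repeat > exon >
intron.  The structural-RNA tier is ordered as listed (a deterministic
tie-break).  Exon/intron assignments split into sense/antisense by comparing
locus strand with gene strand; when both orientations occur at the top
category, sense wins.  Repeat tags carry their subtype, or "Ambi" when loci
overlap more than one subtype.  Tags with zero loci are reported separately
and excluded from the category/length distributions, which cover
genome-matched reads only.

## Expression

RPKM uses the tag's own length as the "kilobase" basis and the sample's
total clean reads (not mapped reads) as the "million" basis — library totals
are the quantity reported alongside read statistics, and the choice is
configurable.  The fold change of a focal sample is its RPKM divided by the
mean RPKM of the other samples, with the denominator floored at a
pseudocount δ = 0.01.  This functional form and δ were fixed by recomputing
the bundled published table of 40 germ-cell piRNA rows from their printed
per-sample RPKMs: all 40 reproduce the printed fold changes within 1%
(residuals are consistent with 2-decimal RPKM rounding), and the rows whose
reference samples are all zero (e.g. 11.95 → 1194.81) pin δ at 0.01.
Upregulation is a plain FC ≥ 2 threshold — single libraries per sample, no
replicate or variance modelling.  Percentages and fold changes are rounded
half-up to two decimals at report time only.

## piRNA clusters

Loci are scanned with windows of 5 kb sliding in 2.5-kb steps.  The
background model is a genome-wide uniform Poisson rate λ = total loci /
total genome length; a window with n loci is candidate-significant when
P[Poisson(λ·window) ≥ n] ≤ α (default 0.05), with no multiple-testing
correction (the plain significance level is the stated operating point).
Overlapping or touching significant windows are merged, and merged
candidates are trimmed to their outermost loci.  A candidate is accepted
only if all criteria hold simultaneously:

* ≥ `min_loci` (6) distinct loci;
* density p ≤ α, where the cluster's p re-evaluates the Poisson tail at its
  locus count;
* strand-bias score ≥ 1.3, defined as W_main / max(W_minor, 1) over weighted
  per-strand locus counts — a deliberately simple ratio statistic isolated
  behind one function so it can be swapped; any definition with threshold
  1.3 must exceed 1 under bias, and flooring the minor strand keeps
  single-strand clusters finite (they score their own weighted size);
* ≥ 75% of weighted loci in the typical piRNA length range 26–32 nt;
* ≥ 75% of weighted loci with the ping-pong 1U/10A signature: T at position
  1 or A at position 10 of the tag as sequenced (1-based; sequences shorter
  than 10 nt classify as negative with a warning).

Loci are weighted 1/(tag's total genomic loci) by default, honouring
clusters supported by infrequently mapped reads; uniform weighting is
available.  The window size was chosen so that planted 1–3-kb clusters are
recoverable and is configurable.  The conjunction is what gives the scanner
its precision: gene bodies and structural-RNA fragment hotspots are often
dense enough to be candidate-significant but fail the length and signature
fractions.

A piRNA call is any tag with ≥ 1 locus inside an accepted cluster; the
origin table counts called piRNAs once each by annotation category.

## Synthetic data generator

The generator emulates the statistical structure this analysis assumes, with
one integer seed driving a single `numpy` generator end to end (identical
inputs give byte-identical FASTA/GFF3/FASTQ output).

**Genome.**  I.i.d. uniform-base chromosomes (composition configurable) with
non-overlapping planted features: piRNA cluster intervals tiled with
same-strand repeat copies, dispersed repeat copies (LINE/CR1-, LTR/ERVL-,
SINE/MIR-like subtypes), gene models with alternating exons/introns, and
structural RNA loci (tRNA/rRNA/snRNA/snoRNA/scRNA/miRNA).  Each cluster and
each dispersed subtype has its own repeat consensus, and copies mutate at 8%
per base: old, diverged repeat families, so 18–44-nt tags map (near-)
uniquely outside their own cluster.  Placement is rejection-sampled; a spec
whose features exceed 80% of the genome, or that cannot be packed, fails
with the offending category named.

**Libraries.**  Reads are drawn per-class from a weight vector over
{cluster piRNA, genic piRNA, miRNA-like, rRNA/tRNA fragments, exon/intron
fragments, background}.  Cluster reads sample a pre-planted set of distinct
loci per cluster (default 600) with lengths peaked at 26 nt (≥ 75% mass in
26–32), main-strand probability 0.95, and rejection-sampled start positions
so the read shows 1U with probability 0.9 and 10A with probability 0.5.
miRNA-like reads are a few high-copy 22-nt species (Dirichlet copy-number
weights over miRNA loci); structural/genic fragments sample a limited pool
of distinct degradation species per feature; background reads are uniform
over the genome.  Adapter read-through appends the full adapter to a
configurable fraction of reads (default 0.10); a low-quality fraction
(default 0.05) draws per-base Phred from the Q8 component of a two-component
(Q35/Q8) normal model, exercising the mean-quality filter with a
controllable discard fraction.

The four example profiles encode the germline/somatic contrast the analysis
targets: the PGC-like profile is repeat-cluster dominated so that unique
tags peak at 26 nt while total reads peak at 22 nt (miRNA mass), and the
modal unique-read category is repeat; somatic profiles (GSC/CEF-like) are
miRNA/rRNA dominated and peak at 22 nt throughout; the StageX-like profile
is intermediate.  The class weights were set by composition arithmetic to
realize those qualitative shapes at the default depth of 50,000 reads.

**What it does not emulate** — and hence what passing tests do not show
about real data: no base-call errors or quality–error coupling, no realistic
repeat consensus sequences or nested/truncated insertions, no ping-pong
5′-overlap pairing between reads, no expression correlation structure across
samples, no paired ends.  Mapping ambiguity in real genomes is far heavier;
here multi-mapping arises only within a cluster's own repeat family.

## Validation oracles and problem sizes

Slow reference implementations (`pirnapipe.validation`) re-derive each
contract by direct enumeration: an all-offsets Hamming scan for the mapper,
enumerate-all-overlaps for annotation priority, and window enumeration with
direct Poisson tail evaluation for the cluster scanner.  The test suite
checks 100% agreement on mixed random/planted/mutated tags (50-kb genomes,
1,000 tags), annotation agreement on 1,000 simulated tags, and
planted-cluster recovery over 20 seeded simulations (1-Mb genome, 3 planted
clusters, 50,000 reads each) at default parameters, requiring sensitivity
≥ 0.8 and precision ≥ 0.9.  `scripts/acceptance.py` repeats these
computations at reporting scale (300 oracle tags, 500 annotation tags, 5
recovery seeds) — sizes chosen to keep a full from-scratch rerun fast while
leaving the statistics stable across seeds.

## Numerical conventions

Coordinates are 0-based half-open internally; GFF3 is 1-based closed on
read/write; BED is 0-based half-open.  All report rounding (percentages,
fold changes) is half-up to 2 decimals and applied only at output.  Window
grids start at 0 with step ⌊window/2⌋; merged candidates inherit the
window-level Poisson mean for their density p.  Cluster output is
independent of input locus order (loci are sorted internally); degenerate
inputs (empty locus sets, zero-depth libraries) return empty results rather
than errors, while a zero-length genome is an error.
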