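# Methods

This note documents the models, defaults and numerical choices behind
`estpipe`, and what the synthetic-data generator does and does not emulate.

## Sequence layer

Sequences are plain strings over the 15 IUPAC nucleotide codes.  ORFs are
read in all six frames from every ATG to the next stop codon, or to the
sequence end — transcript fragments from a fragmented normalized library
frequently lack the stop — with a 30-aa minimum by default ("has ORF" means
any ORF at or above the minimum).  Coordinates are 0-based half-open
internally and 1-based in every written report.  Ambiguous codons translate
to the amino acid when every resolution agrees and to `X` otherwise.  GRAVY
is the mean Kyte–Doolittle hydropathy over scorable residues (`X`/`*`
excluded).  N50 follows the cumulative-length definition: sort lengths
descending, return the first length at which the running sum reaches half
the total.

## Alignment and E-values

`similarity.search_local` is an exact full-dynamic-programming local aligner
(Biopython's `PairwiseAligner`; no heuristic seeding), with default scoring
match +1, mismatch −2, gap open −5, gap extend −2 and a raw-score floor
of 16.  Both strands are searched; the minus-strand hit reports subject
coordinates reversed, as tabular hit formats do.  This aligner is for
desk-scale data; large searches enter through the 12-column tabular reader
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue
bitscore), with query coverage derived on load when query lengths are given.

E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` per pair.  λ is
computed exactly for the ungapped scheme by root-finding on
`Σ pᵢpⱼ exp(λ sᵢⱼ) = 1` with uniform base composition, and reused for gapped
alignments.  K has no closed form; it is fixed at 0.1, an order-of-magnitude
constant.  This is a declared approximation: every decision threshold in the
pipeline (1e−3, 1e−10, 1e−50) is separated by many orders of magnitude from
the scores it gates, so the constant affects no decision, and E-values remain
strictly monotone in score.  Best-hit selection ranks by bitscore, then lower
E-value, then lexicographic subject id — a total, reproducible order.

## Condensation

Clustering edges are hits with identity strictly above 99 % and coverage
strictly above 99 %, where coverage is alignment length over the *shorter*
sequence (symmetric).  Components are single-linkage: contigs "matching each
other" transitively merge.  Each cluster is star-aligned against its longest
member with free end gaps; members are projected onto the anchor's
coordinates, dropping insertions relative to the anchor.  At > 99 % identity
the projection is equivalent to a full multiple alignment except at
anchor-insertion columns, which the substitution-only generator never
produces; on real data with indels the consensus would lose inserted bases
relative to a full MSA (a known limitation).  Consensus columns that are
non-gap in at least half of the members are emitted: unanimous columns keep
their base, disagreeing ones receive the minimal covering IUPAC code.
All-vs-all alignment inside `condense_assembly` is preceded by an exact
15-mer prefilter — pairs sharing no 15-mer cannot reach the 99 % thresholds —
which changes nothing in the result and makes desk-scale all-vs-all fast.

## Homology

Matched/unique splits are directional; the two directions of a reciprocal
comparison are reported side by side and never reconciled into a single
"consensus" count, because many-to-one hits make the directions genuinely
disagree.  Full-length classification measures coverage against the
*reference gene-model* length (a flag restores the query-length denominator
for other analyses) and uses one best HSP per pair — no HSP tiling.
Duplication relationships come from connected components of the bipartite
query–subject graph after filtering at E < 1e−10 and coverage > 90:
(1,1) one-to-one, (1,>1) one-to-many, (>1,1) many-to-one, (>1,>1)
many-to-many.  Both the member-level count (queries inside many_to_* ) and
the component-level count are exposed, since either may be the quantity of
interest.

## SNP calling

Each query unigene is assigned to its best reference model (E < 1e−10),
reverse-complemented if its best hit is minus-strand, and globally aligned
with free end gaps.  Non-gap mismatch columns yield candidate substitutions
on the reference (1-based); indel columns are skipped.  Identical calls
across queries collapse, recording all supporters; positions with more than
one distinct alternate base are "ambiguous" and go to a sidecar, not the
primary output.  A query base that is an IUPAC ambiguity code produces a
call only when *no* resolution of the code equals the reference base, and is
then flagged `iupac_alt`.  Because inputs are consensus transcripts rather
than reads, a single supporting query suffices; no depth or frequency model
is meaningful here.  Output is minimal VCF (CHROM = gene model, INFO carries
supporter ids) plus the 1..9/≥10 per-gene histogram.

## Enrichment

Per bin: the 2×2 table (selected-in-bin k, selected-out n−k, unselected-in
K−k, unselected-out), tested two-sided by summing all hypergeometric
outcomes no more probable than the observed one (scipy's implementation;
verified against exact rational enumeration in the tests).  Two-sided is the
default because both over- and under-representation are reported; sidedness
is a flag.  Bins with fewer than 5 universe members (default) are excluded
from testing and from the correction denominator m.  `p_adjust` implements
Bonferroni (`min(1, m·p)`) and BH step-up (`q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j`)
directly.  Hierarchical mode (a gene in "29.2.1" also counts in "29.2" and
"29") is off by default since annotation tables mix levels.

## Array evaluation

**Probe design.** 60-mers tiled at `round(linspace(L−60−span, L−60, k))`
with `span = min(L−60, 900)` — evenly spaced with a 3′-end bias, the
convention for oligo expression arrays, since labeling walks from the 3′
end.  Candidates outside GC ∈ [0.30, 0.70] or sharing a ≥ 50-nt exact match
with another unigene are dropped; when fewer than 2 survive the survivors
are flagged rather than discarded.

**Pre-selection.** Stage 1 keeps candidates called above background on the
cRNA-like channel, ranked by signal; stage 2 tops up to the target from the
remainder ranked by the gDNA-like channel — genomic DNA hybridizes probes
whose transcripts happened to be absent from the pooled RNA.  At most two
probes per unigene are retained.  With fewer than 100 candidates there is no
stable background fit and all candidates count as above background.

**Mixture.** A two-component Gaussian mixture on log10 intensities, fit by
EM with deterministic initialisation at the 10th/90th percentiles, tolerance
1e−8 on the log-likelihood, at most 500 iterations; the log-likelihood is
asserted non-decreasing at every step.  Components are labelled so
μ_low ≤ μ_high; "above background" is posterior of the high component
> 0.5.  A fit is *effectively unimodal* when Ashman's
D = |μ_high − μ_low| / √((σ₁²+σ₂²)/2) < 2: an EM fit forced onto a single
Gaussian settles near D ≈ 1.2, well below the D ≥ 2 that separable modes
require, so this threshold (rather than D < 1) makes the flag reliable.

**Background subtraction.** When the fit is bimodal, the 5th percentile of
the low-mode observations is subtracted and values are floored at 1 before
logs.  When it is effectively unimodal nothing is subtracted — there is no
separable background, and subtracting bulk signal would clip dim genes.

**Differential expression.** log2, quantile normalization (every sample
forced to the mean sorted vector by within-sample rank), per-gene median
over the gene's probes, then a two-sample t-test with empirical-Bayes
variance moderation: per-gene pooled variances are shrunk toward a
cross-gene prior, `s̃² = (d₀s₀² + df·s²)/(d₀ + df)`, with (d₀, s₀²)
estimated by the method of moments on log s² (scaled-inverse-chi-square
prior), and the t statistic referred to df + d₀ degrees of freedom.  The
moderation is essential, not cosmetic: at three replicates per condition an
unmoderated t has four degrees of freedom and cannot produce p-values small
enough to survive the BH step-up at FDR 0.05, whatever the effect size.  A
plain Welch test remains available (`method="welch"`).  Significance is
|log2FC| ≥ 1 *and* BH-adjusted p < 0.05.  An explicit sample-exclusion hook
exists for outlier replicates; nothing is excluded automatically.

## Synthetic data

The generators are pure functions of `(config, seed)` — identical bytes on
every run — and record complete ground truth, so recovery tests never
re-derive randomness.  Defaults are the study's operating conditions:
read-length means 566 bp (non-normalized) vs 257 bp (normalized); allele
pairs at 99.5 % identity on 20 % of genes; inter-accession substitution rate
0.01/base; signal mixture at log10 modes 1.0/3.0 with σ = 0.3 and 30 %
background weight; 70 % mismatched probes in cross-species mode; planted DE
at |log2FC| = 2 with 3 replicates per condition; planted bin enrichment at
odds 5.

Design choices: base composition is uniform (GC content is not modeled);
substitutions are uniform over the three alternatives; library normalization
is emulated as `abundance^0.2` — a one-parameter surrogate for
duplex-specific-nuclease kinetics that reproduces the flattening without its
chemistry; contig coverage increases with length, as real assemblies show;
planted DE effects are balanced up/down, as stress contrasts are, which also
keeps normalization honest (an all-up contrast would shift whole-sample
distributions); the DE shift is applied only to probes that actually match
their target — mismatched probes report background regardless of expression;
at most 20 % of genes carry planted DE; read ids carry their source gene.
A uniform sequencing-error rate is available but off by default.

Not emulated: 454 flowgram/homopolymer error profiles, isoform structure,
GC-dependent coverage, probe thermodynamics, spatial array artifacts,
dye effects.  Passing tests therefore demonstrate correctness of the
*bookkeeping and statistics* under the stated noise model, not robustness to
every artifact of real data.

## Problem sizes

The test suite and acceptance script run everything at desk scale, chosen so
each statistical check retains its power while the whole suite stays quick:
aligner-vs-oracle on pairs up to 200 nt; exhaustive Fisher agreement for all
tables with N ≤ 25 plus a dense seeded sweep to N = 60 (agreement to 1e−10
everywhere); all 512 bipartite graphs on 3 × 3 nodes; planted-recovery runs
at 25 genes × 3 seeds; mixture recovery at n = 10,000; DE power at 2,000
genes × 100 seeded replicates (25 in the acceptance script); enrichment
type-I over 500 null draws.  Dataset-scale published numbers (10⁶ reads,
46k contigs) require the archived raw data and are treated as documentation,
not test targets; their printed bookkeeping identities are verified instead.

## Known limitations

One best HSP per pair (no tiling) slightly underestimates coverage for
transcripts split across a reference; the star alignment drops
anchor-insertions; K in the E-value is an order-of-magnitude constant;
the moderated test assumes exchangeable per-gene variances; quantile
normalization under very strong asymmetric DE perturbs tail quantiles and
can nudge the realized false-discovery proportion slightly above nominal.
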