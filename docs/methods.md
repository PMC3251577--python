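# Methods

`racenet` implements the computational side of a RACE-array survey of
chimeric RNAs: gene-specific primers amplify cDNA toward the transcript's
5' or 3' terminus, amplified products from pooled reactions are hybridized
to high-density tiling arrays, and contiguous intensity signals
(RACEfrags) are called, filtered, assigned back to their originating
primer and finally assembled into a gene-to-gene connection network whose
structure and artifact content are then analyzed.  This note records the
model choices, parameter meanings and defaults, what the synthetic data
do and do not emulate, and the numerical conventions.

## Coordinates and annotation model

All intervals are 0-based half-open; GFF I/O converts to 1-based
inclusive at the file boundary.  A gene is a locus with one or more
transcripts (sorted, non-overlapping exon lists) and per-transcript CDS
spans.  Projected exons are maximal runs of the per-gene exon union,
classified internal / most-5' / most-3' strand-aware.  Atomic coding exon
projections (ACEPs) are the coding union split at every annotated exon
boundary of the same gene falling inside it, so an ACEP always matches a
real exon sequence rather than a collapsed hybrid of isoforms; primers
are designed inside ACEPs.  Fragment melding merges overlapping *and*
book-ended intervals, consistent with nucleotide-coverage semantics.

## Primer pooling

Pooled RACE reactions must keep pooled primers far apart so array signal
can be attributed to a unique primer.  Because amplification proceeds
from a primer's 3' end, the clearance is asymmetric: `L` nt on the
amplification side and `l` nt on the other (`L = 900,000`,
`l = 90,000` at genome scale; scaled proportionally for synthetic
geometry).  Extending every primer by (L, l) reduces the constraint to
interval disjointness, and the three orientation classes then reduce
exactly to minimum gaps of 2L (head-to-head), 2l (tail-to-tail) and L+l
(head-to-tail).  The minimum pool count per chromosome is the maximum
overlap depth of the extended intervals — the clique and chromatic number
of the resulting interval graph — and the larger value across chromosomes
is used for all, since primers of different chromosomes are pooled
together freely.

Distribution into pools is a greedy coloring in left-endpoint order of
the extended intervals, choosing the least-recently-used conflict-free
pool.  Greedy coloring in this order is guaranteed to succeed with the
minimum pool count on interval graphs; the LRU choice makes it reduce to
a round-robin deal on uniform layouts, which maximizes the minimum
same-pool gap.  Plain round-robin is not used because clipping of
extensions at chromosome edges makes interval lengths unequal, for which
round-robin can produce conflicts even at the optimal pool count.  Ties
in sorting break on primer id for determinism.

## RACEfrag calling

The caller takes per-experiment probe intensities and four parameters:

| parameter | meaning | default |
|---|---|---|
| `I` | percentile intensity threshold; a probe is positive iff strictly above the `I`-th percentile of the experiment's specific-probe intensities | 99.1 |
| `M` | maximum nt gap (end-of-probe to start-of-next) between consecutive positive probes within one fragment | 59 |
| `m` | minimum positive probes per fragment | 5 |
| `c` | boundary convention: `middle` (mid-probe to mid-probe) or `startend` | `middle` |

The defaults are the optimum found by grid search against annotation-
derived quality metrics; negative-control hybridizations are called at
the deliberately sensitive setting `I=99, M=25, m=3, c=middle`.
Percentile thresholding makes tracks self-normalizing, so no cross-array
normalization is performed.  Probes with more than one exact genomic
match (either strand) are excluded before thresholding.

Caller quality is measured as the median, over projected internal exons
overlapped by at least one fragment, of the intersection-over-union in
nucleotides between the exon and the union of its overlapping fragments
(exonic accuracy; internal exons are used because RACE truncates terminal
exons at the priming site).  A reference-free secondary diagnostic scores
donor/acceptor position-weight matrices in two windows (default
half-width 30 nt, not externally prescribed) around fragment boundaries
and reports the best log-odds per site type.  The bundled PWMs are
canonical human donor (9-mer, GT at +1/+2) and acceptor (23-mer ending
AG) frequency matrices compiled from standard splice-site consensus
frequencies; they are plain TSV data files and user-replaceable.  Only
the + strand of the supplied sequence is scanned by default, since RACE
products are strand-ambiguous on the array; both-strand scanning is a
flag.

## Specificity filters

Two artifact channels are removed before assignment.

*USPP filter.*  An in-silico RACE-array simulation runs the protocol over
the known transcript set: a primer primes a transcript wherever its 3'
seed (default 15 nt) matches within 2 mismatches; the product extends
from the priming site to the transcript terminus in the amplification
direction; every probe sharing at least 24 contiguous bases with a
product becomes a simulated positive probe, classed *bona fide* if it
overlaps an exon of the primer's own locus and *unspecific* (USPP)
otherwise.  A fragment is removed iff it overlaps a USPP originating
from a primer of its own pool.  The seed/mismatch/hybridization
thresholds are configurable; the defaults are chosen permissive enough
to expose mis-priming and cross-hybridization without a thermodynamic
model.  Sequence matching is done in genomic + orientation on both
strands of the probe k-mers.

*Negative-control filter.*  Tracks hybridized without RACE amplification
capture signal from abundant transcripts not targeted by any primer.
Negative tracks are called at the sensitive parameter set and any
fragment overlapping a negative-control fragment of the same sample is
eliminated; samples lacking a negative track pass through with a
warning.  Both filters are order-stable and idempotent, and bona fide
simulated probes never cause removals.

## Assignment and the confidence score

Within a pool, a primer is *compatible* with a fragment when it is on the
same chromosome and points at it, and *active* in (pool, sample) when
some fragment of that experiment overlaps it.  Each fragment is assigned
to its single closest compatible primer (nearest-edge distance, 0 on
overlap; ties break to the smaller start, then id) only if that primer is
active; otherwise the fragment is discarded — deliberately, no fallback
to the next-closest primer, because without an underlying generative
model a farther assignment is not defensible.

Fragments with identical coordinates across experiments share an
identity.  For a fragment identity r and locus l, with R the total
occurrences of r across experiments, L its occurrences assigned to l and
P the number of distinct primers of l involved,

    ACS(r, l) = R^(1 + (R - L)) / L^(P + 1)

Lower is more confident: recurrence consistently assigned to one locus
(L close to R) and support by several primers (P > 1) drive the score
down, while promiscuous fragments (large R, small L) are punished by the
exponent on R.  The score is strictly positive, decreasing in L and in P
and increasing in R at fixed L over the valid integer domain (P <= L <= R).

## Network statistics

An edge A -> B in sample t exists when a sample-t fragment assigned to a
primer of A falls within the locus of B.  A pair is *reciprocal* when
both directions exist; *pure* when both directions co-occur in at least
one sample and *composite* when reciprocity is only deducible across
samples.  Gene-gene distance is the nearest-edge gap between loci
(0 when overlapping), binned by default at 150 kb / 1 Mb / 5 Mb.

*Cliques.*  Counts of complete subgraphs of each size (and separately of
maximal cliques, since the two conventions are both in circulation) are
compared with degree-preserving randomized networks generated by double
edge swaps (default 10x the edge count of accepted swaps); enrichment is
observed over null mean.

*Hubs.*  The null redraws the observed number of undirected edges with
endpoint probabilities proportional to gene length x primer count,
honoring the fact that long, heavily primed genes accumulate connections
for trivial reasons.  A gene's connectivity score is observed minus
expected degree (mean over 200 null draws); hubs are scores above a
configurable quantile, default 0.83 so that roughly 17% of genes are
flagged, matching the proportion reported at genome scale.

*Expression coordination.*  Gene expression is the mean over projected
exons of the mean intensity of probes overlapping the exon, per sample.
Pairwise Pearson correlations are compared between connected and
non-connected pairs, stratified by clique membership and clique size, and
adjusted for genomic proximity with a linear model of pair correlation on
a connectivity indicator plus log10 gap — the covariance-adjusted test
standing in for a classical ANCOVA, whose exact form was an open choice.

*Distance power law.*  Primer-to-fragment distances are fitted by the
continuous maximum-likelihood estimator alpha = 1 + n / sum ln(x_i/x_min)
and reported as the negative exponent; a log-log binned least-squares
slope is available as an alternative method tag.  Zeros are excluded and
counted; degenerate (all-equal) samples raise.

## Artifact discrimination

*Two-species mixture.*  In libraries mixing human and fly RNA,
inter-genomic junction reads are artifacts by construction.  The mean
inter-genomic count of the two pure libraries estimates the
sequencing/mapping baseline; its ratio to the mixed library's
inter-genomic count splits artifacts into sequencing vs library
-preparation fractions (summing to 1 exactly).  Under the null that all
chimeras are artifactual, each species' intra-genomic count in a 1:1 mix
should be half the inter-genomic count; the ratio of observed to that
null is the per-species excess factor.  Across a dilution series,
biological molecules decay as 1/d and preparation artifacts as 1/d^2;
expected counts anchor at the d=1 library, and the least-squares slope of
log count on log d classifies the series as linear (slope within 0.3 of
-1), quadratic (near -2) or mixed.

*5C support.*  A connection g1-g2 is detectable by 5C when some
forward/reverse 5C fragment pair overlaps the two loci (either
orientation) and validated when such a pair sits in the top 10% by
interaction score.  The observed validated proportion is compared with
resamples of equally many connections from the universe detectable by
both techniques, drawn within joint distance x length quantile strata
(5 x 5 by default) so the null preserves the connected genes' covariate
distributions.  Because the proportion over a few hundred connections is
a heavily tied statistic, the reported p-value uses the mid-p (tie-split)
convention, which is calibrated under the null where the plain >= count
is markedly conservative; the conservative value is reported alongside.

*Junction sequence analysis.*  For a chimeric junction between genomic
blocks, the duplication length is the forward plus backward exact-match
shift between the sequence flanking the left block and the sequence at
the right block's start — the number of alignments the junction admits;
lengths of 5+ nt are flagged (template-switching-like).  Detection is
exact string equality, matching how such duplications are read off an
alignment.  Splice classes follow the canonical definitions N|GT-AG,
G|GC-AG (requiring the exon to end in G) and N|AT-AC; introns shorter
than 4 nt are non-canonical by fiat.  The six-frame ORF scan reports
ATG-to-in-frame-stop spans on both strands; the default minimum of 100
codons is a conventional threshold, configurable since no external value
is prescribed.

## Synthetic data

The generator builds a scaled-down world: by default two 120 kb
chromosomes, 20 non-overlapping genes of 3-5 exons (140-200 nt exons,
250-500 nt introns, one skipped-exon isoform at rate 0.5), one 5' and
one 3' primer per gene centered in ACEPs, and 25-mer probes tiled every
17 nt.  About 7% of probes are made multi-mapping by copying their
sequence into intergenic space; probes overlapping ACEPs are exempt,
mirroring the genome-wide uniqueness screen applied to primer-hosting
regions in the experimental design (and previously written copies are
protected from being overwritten, so every planted duplicate is real).
Pooling clearances scale to L = 40 kb, l = 4 kb, giving ~8 pools.

Planted networks expand reciprocal pairs, cliques and hub degrees into
directed chimeras: each undirected pair yields two chimeric transcripts
(one per index gene, read out by the primer pointing at the partner)
sharing a sample set, so planted reciprocity is pure by construction.
Array tracks draw log-normal background (log-mean 0, log-sd 1) and add a
linear signal amplitude (default 30) at probes overlapping at least 8 of
their 25 bases (about one third) with a RACE product — the own-gene
product from priming site to terminus plus any planted chimeric target
exons present in the sample; a larger footprint requirement makes
primer-activity detection geometrically fragile at product termini
without adding realism.  Cross-hybridization lights random probes at
rate 0.002, and per sample one abundant untargeted intergenic transcript
(~1.2 kb) lights up in every track of that sample including the
negative controls, exercising the negative-control filter.

Expression matrices induce target pairwise correlations (0.2 connected
vs 0.07 baseline over 16 conditions) with one latent factor per planted
edge plus a global factor; per-gene edge loadings cap so variances stay
valid, which leaves hub edges slightly under target.  5C tables score
one fragment pair per same-chromosome gene pair, boosting connected
pairs into the top decile with a configurable enrichment probability.
Mixture series draw Poisson counts around N1/d + A1/d^2 with d in
{1, 5, 50}.  RT-PCR-like products concatenate the two junction blocks
and locally edit the genome to plant either an exact junction
duplication of 5-10 nt (with forced mismatches pinning the ambiguity
window) or a canonical splice class with duplication length 0; the two
features are planted on disjoint products because a duplication
overwrites the donor-site region.

What the generator does **not** emulate: probe thermodynamics and
GC-dependent hybridization efficiency, read-level sequencing (mixture
data are count-level), repeat structure beyond planted exact duplicates,
overlapping or nested genes, trans-chromosomal chimeras, and
condition-dependent expression amplitude.  Passing the end-to-end
recovery test therefore demonstrates the pipeline's logic — pooling
feasibility, caller geometry, pool-scoped filtering and assignment,
reciprocity bookkeeping — not robustness to the full noise spectrum of
real arrays.

## Problem sizes and numerics

The default end-to-end run (2 x 120 kb, 20 genes, 4 samples, ~8 pools,
~14,000 probes per track) completes in a few seconds and recovers 100%
of planted reciprocal pairs with at most one spurious pair at default
noise.  Grid searches use 12-point grids over I x M x m; clique nulls use
100 randomizations; hub nulls 200 edge redraws; 5C nulls 1,000 resamples
at analysis scale and 200 in calibration checks.  Percentiles use numpy's
linear interpolation; all randomness flows through
`numpy.random.default_rng` seeds, and every generator is deterministic
given its seed.  Degenerate inputs (all-equal intensities, empty grids,
constant expression profiles, graphs with fewer than two edges, all-equal
distance samples) are either signaled distinctly or handled with
documented warnings rather than silently producing numbers.
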