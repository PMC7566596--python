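# Methods

## Coordinates and annotations

All internal coordinates are 0-based half-open; BED is read natively, GTF
(1-based inclusive) is converted on read. Overlap means ≥ 1 bp
intersection on the same chromosome; strand is ignored throughout, since
none of the implemented statistics is strand-aware. The genome length
constant (3,088,286,401 bp, hg38) is the denominator of every genomic
length fraction.

SE–gene classification uses the SE's original interval: *intergenic* if no
gene overlaps it, *embedded* if at least one gene fully contains it,
*partial overlap* otherwise. Boundary extension applies only to embedded
SEs and only over their embedding genes (not all overlapping genes): the
new start is the minimum embedding-gene start, the new end the maximum
embedding-gene end. Extension is idempotent and the extended interval
always contains the original. After extension, SEs with identical
(chromosome, start, end) are collapsed into one record with the union of
ids: distinct SEs inside one gene extend to the same gene body and would
otherwise appear as duplicate network nodes. This collapse is the
mechanism by which an input catalog shrinks after extension (e.g. 912 →
875 in the reference HUVEC catalog); the exact rule used for the original
catalog is not recoverable, so coordinate-identity is adopted as the
minimal defensible criterion.

## Read pairs and feature assignment

A BEDPE record's columns 1–3 are the RNA end, 4–6 the DNA end. Records
with '.' as either chromosome are unmapped, skipped before any denominator,
and tallied. A designated end "maps to" a feature when the alignment-span
intervals intersect by ≥ 1 bp — span overlap rather than a 5′-point rule,
which is robust to read length; an end overlapping k features increments
all k per-feature counts but the pair contributes once to the
any-feature total. Interval queries run by chunked numpy broadcasting per
chromosome, exact for overlapping features and multi-hits; feature sets
here are small (10²–10³) so the dense candidate product is cheap.

## Enrichment statistics

For read-end proportion p and feature-class genomic fraction q, the odds
ratio vs genome average is (p/(1−p))/(q/(1−q)) and the fold of proportions
is p/q. Both are reported: published figures label some ratios "fold
increase of odds" that arithmetically equal the proportion ratio, so the
caller can inspect either. Significance uses a df = 1 goodness-of-fit
chi-square of the observed (in, out) split against the fixed expectation
(n·q, n·(1−q)), without continuity correction; this treats q as known
(genomic lengths are not sampled), deliberately distinct from the 2×2
contingency chi-square used for condition-vs-condition comparisons.
Contingency tables with a zero cell get the Haldane 0.5 correction for the
odds ratio only (flagged); a zero margin is an error. p-values below
2.2e−16 are rendered "< 2.2e-16" by the formatting helper.

## SE–SE networks

Contacts are counted for unordered SE pairs {i, j}, i ≠ j: a pair
contributes iff its RNA end overlaps one SE and its DNA end the other,
with direction collapsed; ends overlapping several SEs contribute to every
qualifying combination; pairs with both ends in one SE measure
self-transcription and are excluded. Raw counts are normalized by the
sample's total uniquely mapped pairs, which makes tables
depth-comparable: scaling raw counts and the total by any constant leaves
normalized counts and the called edge set unchanged.

The interaction threshold is the 95th percentile (linear interpolation) of
the baseline sample's *nonzero* normalized counts — over all possible SE
pairs the distribution is overwhelmingly zero and the percentile would
degenerate. Edges are pairs strictly above the threshold; ties at the
threshold are excluded.

Hubs are nodes with degree ≥ the 95th percentile of the degree
distribution over nodes with degree ≥ 1, with an absolute minimum-degree
override. The tie rule is inclusive (≥), so a constant-degree network is
all hubs. For a multi-time-point analysis the driver pools degrees across
the time-point networks and applies the pooled percentile as one absolute
cutoff — a single realized cutoff across time is what makes a sparse
baseline contribute its one genuine hub rather than its percentile
artifacts, and matches how a fixed degree cutoff is applied in practice.

The degree power law is fitted by discrete maximum likelihood,
P(X = k) ∝ k^(−α) for k ≥ x_min normalized by the Hurwitz zeta ζ(α, x_min),
with α maximized numerically on (1.01, 10) and x_min chosen among observed
degree values (≤ 50 candidates, each leaving a ≥ 10-point tail) to
minimize the KS distance between tail empirical and fitted CDFs. The
log-log CCDF regression slope (≈ −(α − 1)) is reported as a diagnostic.
Fits with KS ≥ 0.1 or a degenerate tail are flagged implausible. This fit
is implemented here and validated against `scipy.stats.zipf` sampling:
α = 2.5 is recovered within ±0.2 at n = 5,000.

## Hi-C summaries

MoC between partitions P (N domains) and Q (M domains):
1 if N = M = 1, else (Σ_{ij} |p_i ∩ q_j|²/(|p_i||q_j|) − 1)/(√(NM) − 1),
lengths in bp; only declared domains enter the sums (gaps are excluded).
Genome-wide values are reported both length-weighted (weight = mean
covered bp of the two partitions per chromosome, so short chromosomes do
not dominate) and unweighted. MoC > 0.75 is the conventional
high-concordance cutoff.

Distance decay: for each distance d = k·resolution in [40 kb, 20 Mb], the
mean of entries at diagonal offset k pooled across supplied chromosomes;
a max distance beyond the matrix extent truncates with a warning. The
log-log regression slope of the curve estimates −β under the power-law
decay expected of a fractal-globule chromosome (β ≈ 1). Within-TAD
fractions snap TAD boundaries to the nearest bin edge, sum the square
block, and divide by the sample's total pairs; sub-bin TADs are skipped
with a warning.

## Single-cell co-expression

"Expressing" means raw UMI count > 0 — detection, invariant to library-
size normalization; no expression threshold is defined in the reference
workflow and detection reproduces its reported per-gene positivity
percentages. QC removes cells above the per-sample upper percentile of
detected genes (99th for cultured, 98th for tissue samples), above the
mitochondrial cap (absolute fraction when ≤ 1, else a per-sample
percentile; mitochondrial genes identified by a configurable "MT-"
prefix), or below the minimum gene count (300). Percentiles are computed
within each sample independently.

The headline statistic conditions on anchor-positive cells: rows =
condition, columns = partner±, OR = (a·d)/(b·c) with the df = 1 chi-square
from the shared contingency machinery. The alternative condition ×
(both-vs-not) table is deliberately not the headline statistic; the full
table is returned so any derived quantity can be inspected. The partner
screen repeats the test over the genes embedded in SEs adjacent to the
anchor's SE in the interaction network (anchor's own genes excluded,
duplicates dropped), ranks by descending OR, ties broken by smaller
p-value then gene id.

## Synthetic generators

The generators define the study conditions at desk scale. Annotations:
non-overlapping 50-kb genes placed uniformly per chromosome on a
90-Mb four-chromosome genome, 60 SEs of 20 kb of which a configurable
fraction (default 0.6) is embedded strictly inside genes, the rest
strictly intergenic. Read pairs: the RNA end is drawn from a genome-wide
density uniform except multiplied by E (default 9, the scale of the real
assay's SE enrichment) inside SEs; the DNA end shares the RNA chromosome
with probability 1 − p_inter (default 0.344, the baseline condition) else
lands on a uniformly chosen other chromosome; designated hub SEs multiply
their DNA-end mass. Read spans are fixed 50 bp, mirroring paired-end
100-cycle reads split over two ends. The closed-form RNA-in-SE
expectation E·q/(E·q + 1 − q) anchors recovery tests.

Cell counts are generated at the Bernoulli level: among anchor-positive
cells the control partner rate is r and the treated rate ω·r/(1 − r + ω·r),
so the contingency OR is exactly ω in expectation — the acceptance surface
is parameter recovery, not count-distribution realism. Positive entries
get 1 + Poisson(λ) counts. Contact matrices are (|i − j|)^(−β) with an
optional (1 + τ) within-TAD boost and optional Poisson resampling at a
configurable depth; the emitted TAD partition is the ground truth for MoC
and within-TAD tests.

What the generators do *not* emulate: transcript-level structure, gene
expression covariance beyond the planted anchor–partner dependence,
chromatin-state heterogeneity along chromosomes, replicate structure, or
mappability artifacts. Passing recovery tests therefore demonstrates the
estimators' correctness under the assumed sampling model, not robustness
to real-data artifacts.

## Problem sizes and numerical choices

Hub recovery runs at 10⁶ pairs with three designated hubs among 60 SEs
(5%, near the real ~3% hub share of 875 SEs) and a depth-matched baseline
sample for the threshold — depth-matching is the stated purpose of the
normalization. Percentiles use numpy's linear interpolation everywhere.
Power-law recovery uses 5,000 degrees; co-expression recovery ~10,000
anchor-positive cells per condition (binomial SEs make log-OR accurate to
a few percent); decay recovery uses a 750-bin 40-kb matrix. The
qualitative time course (rising interchromosomal fraction, growing hub
sets with continuity) runs at 3 × 10⁵ pairs per time point in the test
suite and 10⁶ in the analysis drivers.

## Known limitations

- The extended-SE collapse rule reproduces *a* catalog reduction, not
  necessarily the original one (unverifiable without the original files).
- The percentile-based hub rule caps the hub share near 5% of active
  nodes by construction; designated hubs exceeding that share cannot all
  be recovered, whatever the data.
- The goodness-of-fit chi-square treats genomic fractions as exact; for
  very small feature classes the low-expected-cell flag should be heeded.
- MoC is computed on declared domains only; partitions with large gaps
  are compared only where both declare domains.
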