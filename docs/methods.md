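# Methods

This note documents the models and procedures implemented in `chromaging`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions used throughout.

All genomic coordinates are 0-based half-open (BED convention); "overlap"
means an intersection of at least 1 bp unless midpoint mode is requested.

## Synthetic study generator

The generator (`chromaging.simulate`) emulates a multi-region single-nucleus
chromatin-accessibility study of the aging mouse brain at three ages (2, 9,
18 months), at desk scale.  One global integer seed is split into named
sub-streams (CRC-keyed `SeedSequence` children), so adding a generator never
perturbs draws from existing ones and every output is bit-reproducible.

**Genome and annotation.** Default 5 chromosomes × 20 Mb.  Repressive
(H3K9me3-like) domains are fixed 250-kb blocks placed without overlap until
they cover the requested genome fraction (default 3%, matching the scale of
constitutive heterochromatin domain calls in mouse forebrain).  Fixed-length
blocks were chosen because broad-domain character matters for the overlap
statistics while the true domain-length distribution does not; it is not a
claim about real domain sizes.  TE copies carry subfamily labels; genes
carry biotypes (70% protein-coding, 20% lncRNA, 10% pseudogene) and strands.

**DAR tables.** Background DARs (default 30,000, width 500 bp) are placed
uniformly outside planted hotspot spans.  Their probability of falling in
repressive domains is `coverage × enrichment` (capped at 1): the enrichment
parameter *is* the expected enrichment ratio, so `enrichment=1` reproduces
coverage and `enrichment=0` excludes domains.  Planted hotspots contribute
exactly `n_dars` within their spans; a span that cannot hold its DARs at
minimum spacing is a configuration error.  Directions are up/down with a
configurable up-fraction; domain-interior DARs can be forced predominantly
up to emulate heterochromatin erosion.

Effect sizes are a deliberate design point.  Background DARs draw
|log2FC| = 0.25 + Exponential(0.15); planted hotspot DARs draw
1.2 + Exponential(0.5).  The background mixture spans the hotspot stage's
|log2FC| > 1 counting filter, so only its strong tail (≈0.7%) contributes
to binned density.  This reproduces the sparse-count regime the hotspot
statistic operates in on real data — a few thousand strong DARs over the
~27,000 100-kb bins of the mouse genome is on the order of 0.1 counted
DARs per bin — and it is what makes clustered signal detectable at all: a
dense counted background (tens per bin) would swamp clusters of 50 DARs per
500 kb regardless of the statistic.  All simulated p-values lie below 0.01,
as befits regions already called differential.

**Cells and accessibility.** Cells are drawn per (age, region, replicate)
sample (default 4 regions × 2 replicates × 250 cells) with multinomial
cell-type composition.  Default compositions include three declining
progenitor-like populations (DG progenitor 3% → 0.5% → 0.01%, IOL
2% → 0.1%, an immature-neuron population 4% → 1%) against stable mature
types, echoing the progenitor decline such studies report.  Accessibility
is Bernoulli per cell and peak with age-group-specific probabilities;
differential peaks scale the old-age probability by `2**effect_log2fc`
(9-month cells take the geometric midpoint, giving the gradual trajectory).

**TE counts** are negative-binomial (gamma–Poisson, dispersion 0.1, means
10–200) with a configurable set of planted age-differential subfamilies
(default 20 of 500 at 4-fold).  **Label profiles** are Gaussian reference
profiles; queries add noise of configurable sd and, with a confusion
probability, are generated from the wrong reference cluster, with the true
map returned for scoring.

What the generator does **not** emulate: read-level data and fragment
files, doublets, batch effects, spatial coordinates, peak-width and
domain-length distributions, or correlated accessibility between peaks.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated generative model, not robustness to
the artifacts of real single-nucleus data.

## Differential accessibility

Detection fractions are computed per group on binarized matrices (any
nonzero entry counts).  The test is a two-sided two-proportion z-test with
pooled variance on the young/old fractions; this dependency-free statistic
matches the binarized representation the data are clustered on.  Degenerate
pooled fractions (0 or 1) give p = 1; groups under 2 cells skip the peak
with a warning.  log2FC uses a pseudocount defaulting to 1/(n_young+n_old),
a scale-free shrinkage that keeps empty fractions finite.  BH correction is
applied across the peaks of one call — callers comparing several
(cell type, region, sex) families run one call per family.  Direction is
the sign of log2FC; exact zeros belong to neither direction.  Both
fold-change conventions (0.25 permissive, 0.5 strict) are exposed via
`min_abs_lfc`; the default is the permissive 0.25.

Calibration (fixed seeds, acceptance suite): at 2,000 null peaks and 200
cells per group the raw p-values are uniform (KS < 0.05) and ≤ 2% pass
adjusted p < 0.01; a true 0.2 → 0.4 shift at 500 cells/group is estimated
at median log2FC within ±0.1 of 1.

## Hotspot statistic

Bins are `ceil(length / bin_width)` per chromosome (default 100 kb, last
bin short).  Each qualifying DAR (p < 0.01 and |log2FC| strictly > 1, with
an optional direction restriction; up- and down-DARs are normally scored in
separate passes) increments exactly the bin containing its midpoint —
DARs (~0.5 kb) are tiny relative to bins, so fractional-overlap assignment
would change nothing but determinism.  Counts are raw, not normalized.

Smoothing is per chromosome with kernel weights
`w(j) = exp(−½·(tails·j/(window/2))²)`, `j ∈ [−window/2, window/2]`,
window 20 bins, `tails` 2.5 (the half-window spans 2.5 kernel sd), weights
renormalized over in-bounds bins at every position.  Consequences used as
test oracles: a constant track is a fixed point, interior mass is
conserved, smoothing is monotone in the counts, and output values stay
within the input range.  A window wider than a chromosome truncates with a
warning.

The hotspot threshold is the quantile (default top 1%) of bin scores over
chromosomes carrying any signal, including zero bins (a "nonzero bins
only" alternative is exposed); an optional absolute floor can raise it.
Membership is strictly-greater-than, so ties at the threshold and flat
tracks yield no calls.  Adjacent hotspot bins merge into one call,
annotated with its peak smoothed score, raw DAR content, and domain
overlap.

## Heterochromatin statistics

Enrichment compares the observed overlapping fraction of a region set with
the domains' genome-coverage fraction: the ratio, a closed-form binomial
upper tail P(X ≥ k | n, coverage), and a permutation p that re-places each
region uniformly on its own chromosome (length preserved) with the
+1/(n+1) correction.  Chromosome- and length-preserving permutation
controls for chromosome-level density differences without modeling
covariates the data do not constrain.  An empty domain set is flagged
undefined rather than zero.

The direction split partitions DARs into a 2×2 table (up/down ×
inside/outside domains) per stratum and tests association with a two-sided
exact test computed by hypergeometric enumeration (implemented in-repo;
cross-checked against an independent reference implementation in the test
suite).

Top-gene biotype composition ranks each direction by ascending adjusted p,
ties broken by descending |log2FC| then gene id (the ranking is a
convention, stated rather than inherited), and reports the per-biotype
breakdown of the top *n* plus the combined lncRNA + pseudogene share.
Genes missing from the biotype map are counted as "unknown", not dropped.

## TE quantification

Pseudo-bulk aggregation is an exact integer sum over (cell type, age,
replicate) groups; totals are conserved, and cells with missing metadata
are an error naming the offenders.  Size factors follow median-of-ratios:
each feature's reference is its geometric mean across groups; a group's
factor is its median ratio over features with nonzero geometric mean,
rescaled so the median factor is 1 (identical columns → all factors 1; one
doubled column among equals → factor 2).

The age-differential test permutes replicate age labels.  The per-feature
statistic is the difference in mean log2(normalized + 0.5) between ages;
splits are enumerated exhaustively when few exist (e.g. all C(4,2) = 6 at
2v2, making the smallest attainable two-sided p exactly 2/6), otherwise
Monte-Carlo with the +1 correction.  A permutation test replaces
likelihood-based count models because the aggregation design, not the
test, is the substance here, and permutation is assumption-free at the 2–3
replicates these studies have.  Its price is resolution: at 4v4 the
per-feature floor is 2/70 ≈ 0.029, which can never clear a BH threshold of
0.05·k/m for small k against hundreds of features.  `pool_features=True`
therefore standardizes the statistic by its pooled replicate standard
error plus a median floor (SAM-style) and pools the permutation null
across features, giving p-value resolution of order 1/(splits × features);
this is the mode appropriate whenever FDR control across many features is
the goal.  The pooled mode assumes features are comparably scaled after
studentization — adequate for subfamily counts, checked by the null
calibration test.

## Composition trends

Samples are replicate-level biological units (region × sex × replicate at
one age).  Every observed cell type is reported in every sample, with zero
proportions where absent, so declines to absence remain testable.
"Equal-sample" weighting (default) gives each sample at an age the same
weight, preventing large regions from dominating cross-sample means;
cell-count weighting is available.  The age trend test is a two-sided
Wilcoxon rank-sum on per-sample proportions: exact by enumeration when
both groups have ≤ 12 samples and no ties (8v8 complete separation gives
exactly 2/12,870), tie-corrected normal approximation otherwise; the two
branches agree within ~10% relative at 12v12.  Direction is the sign of
the old-minus-young median difference.

## Label transfer

Profiles z-score each gene across **all** cells jointly (zero-variance
genes are excluded and reported), then average within clusters — so a
single all-encompassing cluster has an exactly zero profile.  Assignment
computes Pearson correlation on the sorted shared-gene intersection
(fewer than 2 shared genes is an error) and takes the arg-max reference;
exact ties leave the query unassigned — ties and ambiguities always fall
toward "no label" rather than a guess.  Subcluster refinement lets only
cells with confidence strictly above 0.85 vote and assigns the modal label
to the whole subcluster only on a strict majority (a plurality mode is
available); the consistency rule labels a subcluster only when one label
covers strictly more than 80% of all its cells.  Both cutoffs are strict
inequalities by construction and tested at the boundary.

## ABC linking

ABC(e, g) = A·C normalized over the gene's candidate elements; genes whose
denominator is zero yield no links, and scores per gene sum to one
otherwise.  Activity is the accessibility signal (or any precomputed
activity column); contacts are taken as provided, with no pseudocount
unless configured.  Candidates are elements whose midpoint lies strictly
within 5 Mb of the strand-aware TSS (start on +, end−1 on −).  The window
and any score threshold are configuration, not claims.

## Problem sizes and numerical conventions

The test and acceptance workloads use a 100-Mb, 1,000-bin genome, 30,000
candidate DARs, 2,000 peaks × ~6,000 cells, 500 TE subfamilies × 8
replicates, 20 clusters × 200 genes, and 200-simulation calibration loops —
sizes chosen so every check runs on one CPU in seconds while keeping the
statistical regime (counts per bin, cells per group, replicates per age)
faithful to the scaled phenomena.  Floating-point conventions: strict
inequalities at all published thresholds (top-1% membership, score > 0.85,
consistency > 80%, |log2FC| > 1 for hotspot counting) and inclusive ≥ for
the DAR effect-size filter; BH adjustment is monotone and order-invariant;
permutation p-values are never zero (+1 correction).  Known limitations:
no modeling of inter-peak correlation, batch structure or doublets; the
pooled TE null assumes post-studentization exchangeability; the two-branch
rank-sum p can differ slightly across the exact/asymptotic boundary.
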