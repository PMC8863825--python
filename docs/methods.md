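# Methods

This note documents the models, conventions and deliberate design choices
behind mirnapipe, stage by stage, including what the synthetic cohort does
and does not emulate.

## Quantification model

Mapping is performed directly against the precursor (hairpin) sequences
rather than a whole genome. The retained read set of a genome-wide mapping
followed by intersection with precursor loci is exactly the set of reads
aligning to precursors, so for counting purposes the two routes coincide;
the difference is that reads from non-miRNA loci are simply unmapped here.
This is a declared simplification: no genome-wide multi-mapping outside
precursor space is modelled, and "N loci" means distinct
(precursor, offset) alignment sites after best-stratum filtering. Two
precursors carrying an identical mature sequence therefore give N = 2 and
each receives half of the read's multiplicity.

Alignment is end-to-end, sense strand only (small-RNA libraries are
stranded), substitutions only, with a default budget of one mismatch.
Candidate sites come from exact occurrences of read segments (pigeonhole:
a read split into `max_mismatches + 1` contiguous segments must match the
reference exactly in at least one segment), then the full read is verified
by Hamming distance; only the minimal observed mismatch count per read is
retained. Reads with more than 10% `N` bases are unmapped and `N` bases
never match. The mapper is provably equivalent to an all-offsets Hamming
scan, and the test suite asserts that equivalence on random reads.

Adapter trimming takes the leftmost read position whose full available
overlap with the adapter prefix (at least 7 nt) stays within a 10%
mismatch budget. Reads with no adapter hit are kept at full length — the
insert may legitimately fill the read — and inserts shorter than 15 nt are
discarded. Note one consequence exercised by the simulator: an insert that
itself begins with an adapter-like prefix is trimmed away; this mirrors
what any adapter trimmer does with such sequences.

Arm assignment uses the read midpoint on the precursor: first half → 5p,
second half → 3p. A midpoint exactly at L/2 goes to 5p; the convention is
arbitrary but deterministic and documented. Annotated mature coordinates
are deliberately not consulted for assignment, only for naming the
(precursor, arm) row.

## Filtering

A miRNA is retained when `count / median(library size) * 1e6 >= 10` in at
least `ceil(0.7 * n_smallest)` samples. Two scopes are available:

* `all` (default): qualifying samples are counted anywhere in the cohort,
  with the quota still derived from the smallest group — the convention of
  count-based filtering tools that must not favour any particular group;
* `smallest`: qualifying samples are counted inside the smallest group
  only — the literal reading of the rule.

Both are exposed because the two readings genuinely differ and either may
be wanted; `all` is the default as the more permissive, group-symmetric
choice. The quota uses the ceiling because the rule says "at least 70%".
The shared denominator is the median library across all samples.

## TMM normalization

The implementation follows the published trimmed-mean-of-M-values
definition: reference sample chosen by the 75th-percentile
count-to-library ratio closest to the mean of those ratios; M and A values
over genes positive in both sample and reference; 30% two-sided trim on M
and 5% on A (rank-based, average ranks on ties); precision weights from
the delta-method binomial variance; factors rescaled to geometric mean 1.
Agreement with an independently coded literal transcription is asserted to
1e-10 on random matrices, and factors on a frozen deterministic matrix
match edgeR 4.0.16 to 1e-9.

Two boundary facts worth knowing. First, duplicating a sample and
doubling its depth changes its factor slightly (≈ 3e-3 at typical sizes):
M-values are depth-invariant but only one of the two terms of the
precision weight rescales, and the reference-sample term does not. The
same deviation is observed in edgeR. Second, log-CPM uses a prior count
scaled to the effective library (`prior * lib_j / mean(lib)`, default 2),
so global depth doubling moves zero-count cells by up to one log2 unit
while leaving expressed cells essentially unchanged; with prior 0 the
transform is exactly scale-invariant.

## Differential expression

Counts are NB(μ, φ) with Var = μ + φμ², one common dispersion φ for all
miRNAs. Tagwise or trended shrinkage is out of scope, a recorded
divergence risk versus analyses that use empirical-Bayes moderation.

*Equalization.* Because the exact test requires identical library sizes,
counts are mapped to pseudo-counts on a common library — the geometric
mean of the effective (TMM-scaled) libraries — by a quantile-to-quantile
NB transform that averages a normal and a gamma continuous approximation
of the NB quantile map. The geometric mean is used as the common size
because it is the scale on which log-library offsets average to zero,
matching the log-ratio construction of the TMM factors themselves.

*Dispersion.* φ is estimated by conditional maximum likelihood: given the
group sum of i.i.d. NB counts with equal means, the within-group counts
follow a distribution depending only on φ; the summed conditional
log-likelihood over genes and groups is maximized by a coarse log-scale
grid followed by bounded scalar refinement, alternated twice with
re-equalization. φ is constrained to [1e-6, 50]; singleton groups carry no
information and are ignored. Recovery is verified on simulated truth
(φ = 0 estimated < 2e-6; φ = 0.1 recovered within ±0.02 at 2 × 20
samples).

*Exact test.* The sum of n i.i.d. NB(μ, φ) variables is NB with size n/φ
and the same success probability, so the group-A sum conditional on the
total t is beta-binomial BB(t, n_A/φ, n_B/φ) — independent of μ. The
implementation evaluates that pmf directly via log-beta functions; in the
Poisson limit (φ < 1e-10) it degenerates to Binomial(t, n_A/(n_A+n_B)).
The two-sided p-value doubles the smaller inclusive tail, capped at 1 — a
well-defined convention for asymmetric discrete nulls (an "as or less
likely" summation is the common alternative; doubling is used here and
matched by the enumeration oracle in the tests). Group sums of
pseudo-counts are rounded to integers before testing. A zero total in
both groups yields p = 1 and logFC = 0.

log-fold-changes are `log2((mean_B + 0.125) / (mean_A + 0.125))` on
pseudo-counts (B relative to A); the small prior keeps logFC finite. The
average log2 CPM uses the common library with a prior of 2. BH adjustment
is the standard step-up, applied per comparison; the significant set is
the union over the three pairwise comparisons at FDR ≤ 0.05.

## Correlation and PCA

Spearman correlations are computed between DE-miRNA log-CPM and each
numeric phenotype with pairwise-complete deletion (a pair needs ≥ 3
complete samples), average ranks on ties, and an undefined (NaN) result —
never 0 — for constant inputs. Correlations are computed on TMM log-CPM
rather than raw counts because rank correlations on raw counts absorb
library-size differences. No p-values are attached; the display is
magnitude-only. Rows and columns are ordered by average-linkage
hierarchical clustering on Euclidean distances of correlation profiles;
inputs are label-sorted first so the ordering is invariant to input
permutation.

The PCA feature matrix concatenates DE-miRNA log-CPM with phenotype
columns, log-transforms phenotypes that are entirely nonnegative
(log(x + 1); signed quantities such as z-scores or ratios enter
untransformed), mean-imputes missing entries per column, and z-scores each
column (ddof = 1). Column-wise standardization of the sample × feature
matrix is used; a literal double standardization across both axes is not
meaningful for PCA and is not implemented. PCA itself is the SVD of that
matrix with eigenvalues s²/(n−1); the sign of each component is fixed by
making its largest-magnitude loading positive, so results are stable
across linear-algebra backends. Contributions are squared loadings as
percentages per component; multi-component rankings weight contributions
by eigenvalue. Group separation on PC1 is summarized by per-group
mean/SD, the best threshold-classifier accuracy between the two
extreme-mean groups, and a flag for whether each remaining group's mean
lies between the extremes.

## Synthetic cohort

The default design mirrors the targeted study layout: three groups of
38/36/84 samples, 300 mature miRNAs (150 hairpins), library sizes uniform
in 1.5–2.5 × 10⁵ reads, baseline abundances spanning 12 log2 units (which
reproduces the familiar pattern of many barely-detected miRNAs and a tail
at 10³–10⁴ CPM), NB dispersion 0.1, and a DE fraction of 19/300 realized
as a 13-miRNA "risk" block with graded offsets (0, +lfc/2, +lfc along the
group order) and a 6-miRNA "health" block with the reverse gradient.
Twelve phenotype variables are generated: eight metabolic-risk-like
parameters rising along the group gradient and four fitness-like
parameters falling along it, each additionally coupled with declared sign
to the z-scored log2 latent abundance of its associated block miRNAs.
Only the association signs are treated as ground truth — Spearman is
rank-based, so effect sizes need no calibration.

Reads are emitted as mature sequence + 3' adapter, truncated to 76 bases,
with substitution errors applied to the insert at the per-base error rate
(default 0.001); the adapter copy in each read is error-free, qualities
are a constant 'I' line, and read names carry only sample and serial so no
truth can leak into the pipeline path. gzip streams are written with a
pinned mtime, making all outputs byte-stable for a fixed design.

What the simulator does *not* emulate: position-dependent error profiles,
ligation bias, isomiRs, degradation fragments, UMIs, hairpin secondary
structure, and per-sample latent biological variability beyond the group
offsets (the NB dispersion is the only within-group noise). Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under the stated model, not robustness to those real-data complications.
A consequence of the last omission: a phenotype association planted on a
miRNA with no group effect carries no recoverable signal, so declared
associations should target differentially expressed miRNAs (the defaults
do).

## Problem sizes and numerics

Simulation-based checks run at 2 × 10⁵ reads/sample × 12 samples for
read-level recovery, 2000 genes for calibration/power, and the full
158-sample default cohort at count level for the correlation/PCA
structure — sizes chosen so each check completes in seconds to a couple of
minutes on a single core while keeping Monte-Carlo noise well inside the
asserted bounds. Numerical tie-breaks are documented where they occur:
5p on exact arm ties, label order on clustering ties, first feature on
loading-sign ties, stable sorts throughout. Dispersion optimization
tolerance is 1e-6 on φ; probability tails in the q2q transform are clipped
at 1e-300 before inverse mapping.

## Known limitations

* Common dispersion only; strongly gene-specific overdispersion will
  inflate the type-I error for the most variable miRNAs.
* The precursor-space mapper cannot distinguish reads that would
  multi-map to non-miRNA genomic loci.
* Mean imputation before PCA shrinks the variance of phenotypes with many
  missing values toward zero, deflating their loadings.
* The exact-test p-value convention (doubled smaller tail) differs from
  the "sum of less likely outcomes" convention in the third decimal for
  very asymmetric group sizes; both are legitimate, one is chosen and
  tested.
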