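# Methods

This note documents the models, conventions and numerical choices behind
`regks`, and what the synthetic-study tests do and do not demonstrate.

## Study design being modelled

The pipeline targets a factorial microarray design: two brain tissues
(hippocampus, cortex), three treatments (noHS = normoxic control, HS =
hypoxia-induced seizures, HS+NBQX = seizures followed by AMPA-receptor
blockade), five sampling times (1, 6, 12, 48, 168 h post-insult), with
cohorts of 4–6 replicate animals per treatment/time cell, each animal
contributing one sample per tissue. Inputs are MAS5-style probeset
intensities (linear scale) with present/absent/marginal detection calls,
a sample design table, a many-to-many probeset→gene annotation, and
signed gene-set collections.

## Preprocessing

**QC statistics.** Per chip: the number of present calls and the 75th
percentile of present-call intensities (marginal calls are treated as
absent — the conservative reading when only present/absent semantics are
guaranteed). Percentiles use linear interpolation between order
statistics; the documented consequence is that a chip whose present-call
intensities are exactly 1..100 has p75 = 75.25.

**Outlier and swap flags.** Chips are flagged when their robust z-score
(median/MAD) on (n_present, log p75) exceeds 5, or when their log2 profile
correlates better with the held-out centroid of the other tissue than
with their own — the signature of a tissue-assignment swap. Flagged chips
are dropped before normalization.

**Normalization.** Each chip is linearly rescaled so its present-call p75
equals a common target. The target is the *median* of the per-chip p75
values: the contract only requires a single common value, and the median
is stable under rescaling of subsets of chips and makes renormalization
idempotent (factors ≈ 1 on already-normalized data).

**Gene collapse.** When a gene maps to several probesets, its measured
intensity per sample is the maximum over those probesets. Expression
*ratios*, by contrast, collapse by the minimum-P rule (below). Unmapped
probesets are dropped with a logged count.

**Standardization and variation filter.** z = (log2 x − mean)/sd per gene
over the chosen samples, with the n−1 (sample) standard deviation.
Zero-variance genes standardize to all-zero with a warning rather than
erroring — synthetic edge cases should not kill a run. The unsupervised
filter is S² = Σ_j (y_gj − ȳ_g)² on log2 data over all samples, which is
large both for genes with many moderate deviations and for genes with a
few large ones; the top 1,000 genes (default) feed the clustered heat map.

**Clustering.** A seeded KMeans partition with clusters relabelled in
first-appearance order and genes ordered within clusters by average-link
hierarchical leaves stands in for a self-organized map. Only the
memberships and the display order are part of the contract; SOM internals
are not reproduced.

## Expression ratios

The ratio estimator takes per-condition means and standard errors of the
mean (from replicate intensities). The measurement model is Gaussian on
the linear scale with the true condition means constrained positive (flat
prior truncated at zero); the reported ratio is the posterior median of
B/A. This contract gives the two properties that matter downstream: the
noiseless limit recovers mean_B/mean_A exactly, and as the errors grow
the estimate shrinks monotonically toward 1 (|log2 r̂| ≤ |log2
mean_B/mean_A| on an equal-se grid, verified against an independent
Monte-Carlo posterior oracle). The median is found by 50 bisection steps
on log2 r with the mixture CDF evaluated by 200-point trapezoidal
quadrature over the truncated posterior of A; the estimate is
antisymmetrized (average of forward and reversed log-medians), which makes
r(A,B) = 1/r(B,A) exact and pins equal-condition ratios at exactly 1.
P-values come from the equal-variance two-sample t-test (on log2
intensities when replicates are available; normal approximation when only
summary statistics are given). Per-gene, per-time ratio profiles computed
at the probeset level collapse to genes by assigning the (ratio, P) pair
of the probeset with the smallest P-value.

## Two-way ANOVA and response-set selection

Treatment (2 levels) and time (5 levels) plus interaction, on log2
intensities at the probeset level. Replicate counts vary between 4 and 6,
so the design is mildly unbalanced; Type II sums of squares are used
because main-effect tests are then invariant to cell-size imbalance. The
implementation computes residual projectors once per model (full,
additive, single-factor) and applies them to the whole gene x sample
matrix, which makes genome-wide scans cheap; it is verified against
statsmodels `anova_lm(typ=2)` on unbalanced designs to 1e-8 relative.
Rows with no residual variance are flagged degenerate with P = 1.

Selection thresholds are config-driven per tissue: either
Benjamini–Hochberg FDR (step-up, selection at adjusted P ≤ q) or raw P.
The defaults mirror the analysis being reproduced: HS response at FDR
0.25 in both tissues; NBQX response at FDR 0.25 in hippocampus and raw
P = 0.01 in cortex (where FDR-based selection is essentially
unconstrained). Selected probesets map to gene symbols and deduplicate.

Overlap of two response sets is referred to the hypergeometric null:
mean n₁n₂/N, se √(n₁n₂(N−n₁)(N−n₂)/(N²(N−1))), and an upper-tail
P(X ≥ k) summed from log-probabilities via logsumexp, stable down to
P ≈ 10⁻³⁰⁰ and beyond (the log10 tail is also reported).

## Regulated KS enrichment

**Ranks.** Descending (rank 1 = largest log2 ratio); ties break by gene
symbol ascending. Reproducibility was preferred over midranks because the
step-point evaluation below requires integer ranks.

**Signed deviations.** For a regulatee group occupying ranks r₁ < … < r_k
in a universe of n, F_sample(r) − r/n is evaluated on the discrete rank
grid at both sides of every member step (r = r_i and r = r_i − 1); the
deviation d is the signed value at the maximum absolute deviation. All
candidate deviations are exact multiples of 1/(k·n) and are compared in
integer arithmetic, so argmax ties are resolved exactly, not at float
precision: ties in |d| break toward the group's coherent sign (+ for
up-regulatees, − for down-regulatees), then toward the smallest r. The
sign preference is what makes the statistic exactly invariant under the
mirror map (negate the profile, swap the groups); a role-blind tie-break
provably breaks that invariance on midpoint ties.

**Combined statistic.** d_UpDown = (k_u·d_u − k_d·d_d)/(k_u + k_d). This
closed form is adopted as the unique membership-proportional linear
combination that is bounded in [−1, 1], continuous as either k → 0, and
weighs each group by its size.

**P-values.** Monte-Carlo permutation of set membership: k_u + k_d
distinct ranks are redrawn uniformly from the universe (rejection
sampling of duplicate rows when k² < n, chunked partial argpartition
otherwise), the first k_u treated as up-regulatees. P is the fraction of
permuted statistics ≥ the observed one; the resolution floor is 1/n_perm
and a count of zero is reported as 0 (meaning P < 1/n_perm). The default
is 10⁵ permutations for a single set; collection screening defaults to
10⁴ and shares null distributions between sets with equal (k_u, k_d),
since the null depends only on those sizes. Profile-label permutation
(which would preserve gene–gene correlation) is out of scope.

**Enrichment scores.** C_L = F_up(x*_u)/x*_u, the chord slope of the
up-regulatee CDF from the KS-plot origin to its maximum-deviation point;
C_R = (1 − F_down(x*_d))/(1 − x*_d), mirrored from the upper-right
corner. An empty group scores the neutral value 1 (so sets with k_d = 0
always report C_R = 1); an argmax degenerate at a plot corner moves to
the adjacent step with a warning. Chord rather than local slope was
chosen: "local" slope of a step function is ill-defined, and the chord
reproduces the expected neutral behaviour (uniformly scattered regulatees
score ≈ 1) and the k_d = 0 ⇒ C_R = 1 pattern.

**Leading edges.** Up-regulatees with rank ≤ r*_u, down-regulatees with
rank > r*_d, where r* is the discrete argmax grid point of each group.

**Screening.** Each set is restricted to the profile universe (skipped
with a warning if nothing remains; unsigned sets are treated as all-up).
FDR is Benjamini–Hochberg within each source collection separately, and a
set is selected when FDR < 0.25 and max(C_L, C_R) ≥ 2 (both defaults
configurable).

**KS plots.** Step coordinates of each group's CDF against population
fractional rank, plus a two-sided null band of half-width equal to the KS
critical value at the requested confidence for the total membership k —
computed from the exact finite-sample distribution (`scipy.stats.kstwo`),
so band coverage on random sets is close to nominal (slightly
conservative because ranks are drawn without replacement from a finite
universe).

## Post-processing

The membership matrix keeps the selected sets as rows and, as columns,
the union of their leading-edge genes restricted to genes occurring in at
least 2 selected sets (so every retained gene is corroborated by more
than one significant context). Row/column display orders reuse the seeded
clustering machinery. The pathway-relevant list is the exact intersection
of those membership genes with the ANOVA response union. The
epileptogenic set intersects, per tissue, the HS response with the NBQX
response and unions across tissues, retaining provenance; the selection
is sign-blind, so NBQX-induced and NBQX-repressed genes both qualify.
Fisher-exact enrichment of discrete sets against the epileptogenic set
uses the one-sided hypergeometric upper tail with the declared background
size and a P < 0.01 cutoff; it agrees with the response-set overlap
statistic by construction and with exhaustive enumeration on small
universes.

## Synthetic studies

Gene-level log2 signal is additive Gaussian (log-normal intensities) —
the simplest model consistent with the z-scoring and equal-variance
t-tests used downstream:

baseline ~ N(8, 1.5²); a monotone developmental ramp of ±2 log2 units
across the five sampling times for 15% up / 15% down genes; a
hypoxic-seizure effect of 1.5 log2 units on 10% of genes (2:1 up:down)
scaled by temporal weights (0.6, 0.8, 1.0, 0.5, 0.3) so modulation peaks
at 12 h; an NBQX effect of 1 log2 unit on half of the HS genes (70%
further-up, 30% reversing) applied only to HS+NBQX samples; per-sample
chip effects (sd 0.15), per-gene-sample noise (sd 0.35) and per-probeset
noise (sd 0.15, 1–3 probesets per gene sharing the gene signal, which
exercises both collapse rules); 20% of genes carry a tissue-specific
offset (sd 1) that gives the two tissues distinct centroids for the swap
check. Detection calls are thinned with P(absent) a logistic decreasing
function of log2 intensity (midpoint 5.5, scale 1). Replicate counts are
drawn uniformly in 4–6 per treatment/time cohort and shared by the two
tissues (one animal, two samples). Seizure phenotypes for hypoxia-treated
animals: latency to first seizure exponential with mean 114 s; seizure
count normal with mean 10.6 and sd 2.9, truncated at 0 and rounded.

Gene sets (100 by default, sizes 10–30, one third down-regulatees) are
drawn either uniformly (null sets) or, for the 20% truly enriched sets,
with each member coming from the planted HS-up (up slots) or HS-down
(down slots) pool with probability 0.9 ("purity"). Effect sizes are
calibration choices — the emulated study reports only that individual
fold-changes were moderate — chosen so that the documented strong-signal
configuration is comfortably detectable while null configurations stay
exactly null.

What the generator does *not* emulate: probe-level (PM/MM) structure and
the MAS5 algorithm itself, spatial chip artifacts, intensity-dependent
variance (noise is homoscedastic in log space), correlated gene modules
beyond the planted effects, and annotation errors. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability under the stated noise model, not robustness to every
failure mode of real microarray data.

## Problem sizes and defaults in the automated checks

The test suite and the acceptance script run the generator at its default
scale (2,000 genes, ≈150 samples, 100 gene sets) for recovery and
calibration checks, with 2,000–50,000 permutations depending on the
resolution each check needs; exhaustive enumerations cover all regulatee
placements with k_u, k_d ≤ 3 on universes n ≤ 8 and brute-force oracle
comparisons cover 500 random instances with n ≤ 12. End-to-end
determinism is checked by hashing every pipeline output into a manifest
and comparing two runs byte for byte.

## Known limitations

- The permutation P-value is Monte-Carlo, not analytic; tail resolution
  is bounded by 1/n_perm.
- The ratio estimator is a documented contract (truncated-Gaussian
  posterior median), not a reimplementation of any specific published
  estimator's internals; its qualitative properties (noiseless limit,
  shrinkage, antisymmetry) are the tested surface.
- FDR control is plain Benjamini–Hochberg, assuming independence or
  positive dependence across probesets / gene sets.
- Paper-scale dataset-specific gene counts require the original data and
  are not reproduced by the synthetic studies; only structural and
  statistical properties are asserted.
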