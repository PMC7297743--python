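# Methods

## The quantities and how they are computed

**Coefficient of variation.** Everywhere in the package CV = s/x̄ with the
sample SD (n−1 denominator). The convention is load-bearing: with the n−1 SD,
the mean and SD/√9 of each population's nine printed trait CVs reproduce the
shipped summary table's iFD_CV and SE to the printed precision for all 13
populations; the population-SD variant does not (e.g. 0.041 instead of 0.044
for KW). A CV requires at least two values and a nonzero mean; both violations
raise rather than return a silent NaN.

**iFD_CV.** The population-level index is the unweighted arithmetic mean of
the nine trait CVs and its SE the SD of those CVs over √9. All nine CVs are
required; where a trait could not be measured in a population the caller
supplies an imputed CV explicitly (`ifdcv(..., impute={...})`). The shipped
table carries one such case (KW's fluorescence traits, published as
regression-approximated values); the package treats those numbers as data and
does not re-derive them, since the approximating regression was never
specified.

**Outlier screen.** Trait records more than 4 pooled SDs from the pooled mean
(all individuals, all populations) are nulled in a single pass; the screen is
not iterated, so a value that would only become extreme after the first
removal survives. Removing an F<sub>v</sub>/F<sub>m</sub> record also removes
the same individual's PI record: both derive from one fluorescence
measurement, so an erroneous reading discredits both. Rows are never dropped —
values are nulled and every removal is returned in a report, keeping
row-count bookkeeping exact.

**Collinearity screens.** Pairwise Spearman correlations (average ranks on
ties, pairwise-complete observations) over pooled individuals (traits) or
pooled replicate records (factors); a pair with |r| > 0.7 flags the
second-listed member for removal. The environmental screen also always drops
zero-variance factors, and accepts an explicit `drop_list` override because
the reference analysis excluded one factor at r = .50 — a judgement call no
threshold reproduces.

**HD.** Per location, the CV of each retained factor across its 1–5 replicate
plots; HD is the mean of those CVs and the SE their SD over √(factor count).
Slope exposure is circular (degrees), but enters as a plain non-negative
number because that is what a CV framework admits; the output flags the column
(`attrs`) since the CV then depends on the 0° reference. HD is invariant to
rescaling any factor's units, which the tests assert.

**Genetic diversity.** H<sub>e</sub> = 1 − Σp² per locus from allele
frequencies computed over individuals typed at that locus; H<sub>o</sub> the
heterozygote fraction among typed individuals; Shannon's I = −Σp·ln p;
N<sub>A</sub> the allele count; P<sub>Ap</sub> alleles absent from every other
population (counted directly, no rarefaction). Multilocus values are
unweighted means over typed loci with SE = SD/√loci. The small-sample
correction 2N/(2N−1) for H<sub>e</sub> is available (`unbiased_he=True`) but
off by default — the shipped GD column matches the uncorrected convention of
the toolkit that produced it. Individuals typed at fewer than 4 of 9 loci are
excluded before any index.

**Nei standard distance.** D = −ln I<sub>N</sub>, with the identity's
numerator and both denominator terms summed across shared loci *before* the
ratio (the "standard" form), not averaged per locus. Disjoint allele sets give
I<sub>N</sub> = 0 and an undefined (NaN) distance rather than infinity.

**PCoA.** Gower double-centering of −½D², symmetric eigendecomposition, axes
ordered by eigenvalue. Negative eigenvalues (non-Euclidean inputs — Nei
distances generally are) are reported, never clipped; coordinates are returned
for positive axes and percent variance is relative to the positive eigenvalue
sum. The implementation is ~20 lines of linear algebra and is cross-checked in
the tests against scikit-bio's PCoA as an independent oracle.

**Saturation curves.** For n = 1..N, 100 simple random subsets *without*
replacement per step (with-replacement behind a flag); the statistic is
recomputed from scratch on each subset — allele frequencies included, so a
private allele carried by one individual leaves the curve as it should. At
n = N the subset is the full sample: the mean equals the plain statistic and
the SD is exactly 0. n = 1 rows are emitted as NaN for CV-based statistics.
The onset report (first n from which successive means change by <2% of the
full-sample value) is a labelled heuristic for reading the curve, not a test.

**Regression layer.** OLS with intercept via statsmodels. AIC uses the
convention n·ln(2π·RSS/n) + n + 2(k+2) (error variance counted as a
parameter, as R's `AIC()` does); only AIC differences are ever consumed.
Backward elimination drops the predictor with the largest p among those with
p > .1, breaking ties by smaller |t| then name order, and logs AIC and the
nested-model F test at every step; eliminating everything returns a flagged
intercept-only model. Variance partition is the share of absolute
standardized coefficients, |β<sub>i</sub>|/Σ|β<sub>j</sub>|·100 — the only
definition that reproduces the reference partition (67.42%/32.58%) from the
shipped table, hand-verified; sequential-SS and LMG decompositions are out of
scope. Trait-level models regress ln(CV) on HD or GD (natural log; R² is
base-invariant) and report a Shapiro–Wilk p for the response without ever
acting on it. The trait-CV × factor-CV correlation grid uses Pearson on
ln(1+CV), the +1 keeping near-zero CVs finite and the transform monotone.

**Geodesy.** Vincenty's inverse method on WGS84 (a = 6378137 m,
f = 1/298.257223563) iterated to 1e−12, validated against the 1° meridian arc
(110.574 km). Near-antipodal non-convergence falls back to the great-circle
distance with a warning (error < 0.6%); the package's mid-latitude use never
reaches it. One reproduction note: the mean pairwise distance over the 13
reference locations is **118.2 km** (SD 126.4; 66.1/29.5 excluding the distant
location KW). The values of ~133 km (SD 124; ~80/41 without KW) sometimes
quoted for this design arise from supplying (latitude, longitude) columns to a
routine that expects (longitude, latitude); `pairwise_distance_summary(...,
axis_order="lonlat")` reproduces them exactly (133.08/124.24 and 83.3/40.9)
so the provenance of the discrepancy is checkable rather than mysterious.

**Moran's I.** I = (n/W)·Σw<sub>ij</sub>z<sub>i</sub>z<sub>j</sub>/Σz<sub>i</sub>²
with binary distance-class membership weights, row-unstandardized. Two-sided
permutation p per class: 2·min(P(I* ≥ I), P(I* ≤ I)) with the +1 correction,
capped at 1; values are permuted over locations, fully seeded. Classes are
equal-width bins of the caller's increment — at 13 locations no single
increment keeps every class populated, so empty classes are reported as NaN
rather than hidden.

## The synthetic generator

`simulate()` emulates the reference sampling design: 13 populations × 20
individuals, 5 environmental replicates per location, 9 diploid loci with a
0.10 missing-call rate (≈90% loci coverage), coordinates on a ~10 km grid plus
one distant outlier location exercising the exclusion path.

Causal structure: each location has a heterogeneity level h (default
linspace 0.05–0.40 — the HD range of the reference populations); replicate
factor values are lognormal with log-SD h, so measured HD ≈ h. Each population
has a target expected heterozygosity (default linspace 0.45–0.80, decoupled
from h by a seeded permutation so the two predictors stay identifiable), hit
by drawing per-locus allele frequencies from a symmetric Dirichlet whose
concentration solves E[1 − Σp²] = target; genotypes are Hardy–Weinberg draws,
and an optional selfing rate copies the first allele to depress H<sub>o</sub>
below H<sub>e</sub>. Individual trait values are lognormal with log-scale SD
σ = a·h + b·H<sub>e</sub> + ε (defaults a = 1.0, b = 0.5, ε ~ N(0, 0.02²)),
so the true CV is the analytic √(exp(σ²) − 1) and recovery can be checked in
closed form. Lognormal draws guarantee positivity, so every CV is defined;
F<sub>v</sub>/F<sub>m</sub> gets a 0.05 σ-multiplier (a bounded physiological
ratio varies an order of magnitude less than morphological traits) and a
defensive cap at 1.0.

The default couplings were fixed at design time so that, at the study's own
n = 13, the end-to-end pipeline keeps both predictors with positive
coefficients and ranks HD above H<sub>e</sub> in ≳90% of seeds; the stronger
a = 2, b = 1 setting used in the recovery tests passes the ≥80% bar with
margin and reaches essentially 100% at 50 populations.

What the generator does **not** emulate: spatial genetic structure beyond the
coordinate layout, trait–trait correlation (traits are conditionally
independent given σ), circularity of slope exposure, seasonal trait drift, and
measurement error with trait-specific distributions. Passing tests therefore
demonstrate that the pipeline recovers the assumed statistical structure, not
that real populations obey it.

## Problem sizes and numerical choices

The reference analyses are desk-scale (13 populations) and run in
milliseconds. Test simulations use the design's own sizes: 100 seeds for the
recovery properties (~15 s), 20 seeds at 50 populations, 200-resample
permutation checks for the correlogram's type-I calibration, 1000 resamples in
the example correlogram. Degenerate inputs fail loudly: zero-mean CVs,
constant vectors in z-transforms and Moran's I, rank-deficient designs (the
error names the most collinear column pair), undefined distance-matrix
entries in PCoA.

## Known limitations

- The outlier screen is single-pass by design; an iterated screen would need a
  stopping rule the reference procedure never stated.
- P<sub>Ap</sub> is a raw private-allele count; it is sample-size sensitive
  and not rarefaction-corrected.
- The individual-level genetic distance (allele-sharing) is a documented
  approximation; GUI toolkits implement several variants and the exact one
  behind the reference ordination is unknowable from the published record.
- `saturation_onset` formalizes a visual judgement ("the curve flattens") and
  should be read as such.
- The correlogram's increment is a required analysis choice; no default can
  keep every class populated at n = 13.
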