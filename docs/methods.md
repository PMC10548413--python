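# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Genotype filtering and coordinates

VCF records are filtered in a fixed order — biallelic SNP, missing-call
rate < 20%, minor-allele frequency > 0.01 (non-missing alleles only),
observed heterozygote fraction ≤ 0.5 — so retained-locus counts are
invariant to record order.  The heterozygosity rule uses the *observed*
heterozygote fraction among called genotypes, since its purpose is to
remove collapsed paralogs.  Internally all coordinates are 0-based
half-open; VCF and methylation positions (1-based) are converted on
read.  This makes the 10-kb feature-proximity join unambiguous: a
feature is attached to a hit iff the hit position lies in
[start − w, end + w) with w = 10 000, i.e. the window is inclusive on
both flanks (a hit exactly w bp beyond a feature edge still counts).
Missing dosage is a −1 sentinel in an integer matrix; every statistic
documents its own missing handling rather than imputing globally.

## Diversity and differentiation

Per locus within a population: π = 2p̂q̂·2n/(2n−1) (the unbiased
small-sample form), H_O the heterozygote fraction, H_E = 2p̂q̂.  π and
H_O are averaged over loci with at least one call; because RAD data
carry no callable-site totals the output is labeled *per-SNP* π, not
per-base.  F_IS = 1 − H̄_O/H̄_E uses the ratio of means, which is
stable when many loci have low minor-allele frequency.

Differentiation is the Weir–Cockerham (1984) estimator: per-locus
variance components a (among populations), b (among individuals
within), c (within individuals) computed from sample sizes, allele
frequencies and observed heterozygote counts; the multi-locus θ is the
ratio of sums Σa/Σ(a+b+c) — not the mean of per-locus ratios — which
is the standard choice and the one that makes θ = 1 exact for fixed
alternate alleles.  Pairwise entries drop loci lacking calls in either
population.  The estimator can go slightly negative at θ ≈ 0; values
are reported as computed.

PCoA is classical Torgerson scaling (double-center −D²/2,
eigendecompose, scale by √λ); negative eigenvalues are reported and
their axes dropped.  The default genetic distance for ordination and
Mantel tests is linearized F_ST, F/(1−F), with F ≥ 1 clamped just
below the pole; an individual-level allele-sharing distance is
available for individual ordinations.

## Mantel tests

Geographic distance is the haversine great-circle distance (Earth
radius 6371.0088 km), log-transformed off-diagonal for the IBD test.
Environmental distance standardizes the climate variables, takes the
leading principal components (default 3) of the correlation structure,
and measures Euclidean distance on the scores; collinear variables are
first pruned greedily at |r| < 0.8 (the member of the worst pair with
the larger mean absolute correlation is dropped; ties keep the earlier
column).  The Mantel statistic is the Pearson correlation of
upper-off-diagonal vectors; the null jointly permutes rows and columns
of the second matrix; p-values are one-sided upper-tail
(1 + #{r_perm ≥ r_obs})/(1 + n_perm), matching the ecological
convention for positive association, with a two-sided option.  The
partial Mantel correlates the residuals of simple regressions of each
matrix on the control matrix and permutes the *first raw matrix* — the
simplest standard permutation scheme; residual-permutation variants
exist but are not implemented.

## ABBA-BABA

With per-population derived-allele frequencies p1, p2, p3 and the
outgroup treated as fixed ancestral, each locus contributes
abba = (1−p1)p2p3 and baba = p1(1−p2)p3; D is the ratio of summed
differences to summed totals.  This frequency-weighted form is the
appropriate one for population allele-frequency data (site-pattern
counting is a special case at fixed frequencies).  Without an outgroup
population the global minor allele is declared derived; this folding
preserves the P1↔P2 antisymmetry and keeps E[D] = 0 under the
exchangeable null.  Standard errors are a delete-one jackknife over
contiguous blocks (default ≈ 20 blocks in input locus order);
|Z| ≥ 3 is flagged, and Dmin reports the trio arrangement with the
smallest |D| (ties keep the canonical order (P1,P2;P3), (P1,P3;P2),
(P2,P3;P1)).  Note that under a star-shaped population history an
admixture pulse between two populations leaves the (A,B;C) arrangement
near zero, so Dmin is conservative by construction there — only
tree-like histories give all three arrangements signal.

## F_ST outlier scan

The neutral null is the Balding–Nichols island-model approximation:
ancestral frequency p ~ U(0.01, 0.99), per-population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), genotype class counts binomial at the
observed sample sizes.  This reproduces the F_ST–heterozygosity
relationship the test conditions on without external coalescent
software.  F is calibrated by bisection so the simulated trimmed mean
of per-locus θ matches the observed trimmed mean (default 5% per
tail, trimmed on *both* sides of the comparison — trimming only the
observed side would bias the calibration low, because the per-locus θ
distribution is right-skewed).  Observed loci are then scored against
equal-count heterozygosity bins (default 20) of the null cloud:
p_upper = (1 + #{null θ in bin ≥ obs θ})/(1 + bin count), flagged when
p_upper ≤ 1 − confidence (upper tail only — divergent selection; a
two-tailed option exists for balancing-selection scans), with BH
q-values over all loci.  Equal-count bins stabilize the tail
quantiles; observed He outside the simulated range falls into the
nearest bin with a warning.  A hierarchical (grouped) null is not
simulated; the single-level island model is the stated approximation.

## Linear mixed model

Kinship is the standardized cross-product K = ZZᵀ/m over variable
features (mean-imputed missing values, unit-variance columns, negative
eigenvalues clipped).  Note K1 = 0 by construction — centering puts
the all-ones vector in the null space.

The association model per marker is y = μ + xβ + g + e with
Var(g) = Kσ²_g, Var(e) = Iσ²_e, fitted in the eigenbasis of K.  The
variance ratio δ = σ²_e/σ²_g is profiled on the intercept-only model
over a 100-point log grid on [1e−5, 1e5] refined by golden section,
then reused for every marker (the EMMAX/P3D approximation — orders of
magnitude faster, negligible difference at these sample sizes).  The
profile criterion is *REML*, not raw ML: because K annihilates the
intercept direction, the ML profile diverges as δ → 0 (the intercept
absorbs a zero-variance component exactly) and pins δ at the boundary,
which demonstrably miscalibrates every downstream p-value; the
restricted likelihood cancels the offending terms.  Each marker then
gets a two-parameter GLS fit with a Wald t test on n − 2 df, which
reduces *exactly* to OLS when K = I.  The response is the climate
variable and the marker the explanatory variable — the orientation
that lets one kinship eigendecomposition serve every marker.

Genome-wide thresholds: Bonferroni α/m as the conservative reference,
and a permutation threshold — each of (default) 200 repeats draws
(default) 10 000 markers, permutes the response across samples with
the kinship held fixed, rescans, and records the minimum p; the
threshold is the α-quantile of the minima.  Permuting the response
(rather than markers, and without refitting K) is the cheapest scheme
that preserves the marker correlation structure.

SMV filtering applies, in order: depth < min_depth → missing; missing
fraction > 10% → site dropped; observed level range < 10 percentage
points → site dropped.  The EWAS uses methylation-based kinship; the
SNP GEA uses genotype-based kinship and BH q ≤ .05 by default.

## Gradient forest

Each locus's population allele frequency is regressed on the climate
variables with a random forest (default 500 trees, ⌈P/3⌉ candidate
predictors per split, leaves ≥ 2 samples — sensible at a dozen sites;
scikit-learn supplies the forests).  Fit quality is out-of-bag R²;
loci with R² ≤ 0 are excluded from aggregation.  Every split's
impurity decrease lands in the bin (default 201 per predictor,
spanning its observed range) containing the split threshold; per-locus
bin masses are normalized to sum to the locus R² and averaged over
included loci, so duplicating loci leaves the turnover unchanged.
Cumulative sums of the bins give per-predictor turnover functions
(0 at the range minimum); climate transforms by linear interpolation
within bins, clamping outside the fitted range (clamp events logged —
extrapolation is a known failure mode of offset methods and is
deliberately refused).  Conditional importance for correlated
predictors is *not* implemented; importances are marginal, which the
output metadata states.  Offsets are Euclidean distances in the
transformed space; the forward offset minimizes over destination
sites, so forward ≤ local holds identically.  Raw cumulative
importances are kept unnormalized per predictor, so high-importance
predictors dominate offsets, matching the method's standard behavior.

## Synthetic data

The generator emulates the *structure* of a range-wide RADseq +
bsRADseq study, not any real species: sites along a southwest–northeast
axis with linear climate trends plus site noise; island-model neutral
SNPs via Balding–Nichols at a target F_ST; adaptive loci whose
per-population frequencies are logistic in a standardized driver
variable (clines act on frequencies, which is what GEA and gradient
forest can detect); an optional one-way admixture pulse for
introgression tests; methylation as logit-normal proportions with a
spatially structured population random effect (exponential decay,
500-km range), negative-binomial depth and binomial level sampling.
Defaults mirror the emulated design: 13 populations × 12 diploids,
five bioclimatic variables (BIO2, BIO4, BIO8, BIO16, BIO19), one
methylation sample per population, future scenarios displaced along a
fixed per-variable vector scaled by an emission-severity factor.

What it does not emulate — and what passing tests therefore do not
show about real data: linkage disequilibrium between loci (all loci
independent), sequencing error, reference bias, hierarchical
population structure beyond the single-level island model, and any
mechanistic link between methylation and genotype.  Null-calibration
results transfer to real data only to the extent the island model
approximates the real covariance of allele frequencies.

## Problem sizes and determinism

The bundled analysis scripts and the acceptance script run a
scaled-down study (4000 neutral + 40 clinal loci, 2000 methylation
sites, 300-locus gradient-forest fits at 300 trees, 10⁶-locus null
clouds) chosen so the whole battery completes in minutes on one CPU
while keeping every Monte-Carlo band meaningful.  All generators and
permutation tests are pure functions of explicit seeds; the pipeline
derives per-stage seeds from a master seed via
SeedSequence([master, stage_index]), so adding or removing stages
never shifts another stage's stream.
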