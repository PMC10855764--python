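# Methods

This note records the models, parameter choices and numerical
conventions behind `cheesevoc`, and what its synthetic data do and do
not establish about real measurements.

## The analytical problem

X-ray irradiation of surface-ripened cheeses changes their volatile
organic compound (VOC) profile: radiolysis of lipids produces
hydrocarbons that are absent in untreated samples, while oxidation
products (alcohols, carboxylic acids, methyl esters, ketones, lactones,
sulfur compounds) are produced and degraded by competing dose-dependent
reactions, typically peaking near 4.0 kGy. The package implements the
complete data-analysis chain such a study needs: turning integrated
GC–MS peaks into a comparable feature table, optimizing the headspace
solid-phase microextraction (HS-SPME) step by designed experiment, and
asking — with honest validation — whether the volatile fingerprint
discriminates treated from untreated cheese and between dose levels.

## Chromatographic processing

**Retention indices.** Linear retention indices are computed against a
C7–C30 n-alkane ladder by piecewise-linear interpolation,
`LRI = 100·[c_n + (t − t_n)/(t_{n+1} − t_n)·(c_{n+1} − c_n)]`, which is
exactly `100·n` at every anchor and handles ladders with missing
alkanes. No extrapolation is allowed outside the ladder span: an
out-of-range retention time is an error, not a guess.

**Annotation.** A peak is assigned to the reference compound with the
nearest reference LRI if the gap is within a tolerance, default 10 index
units — a typical inter-laboratory spread on apolar to mid-polar
columns; the value is configurable and deliberately conservative. Exact
ties resolve lexicographically, with a warning.

**Normalization.** Every analyte area is divided by the
internal-standard area (3-octanol, quantifier *m/z* 59) of the same
run; the IS peak must be unique and positive. Normalization is
scale-invariant by construction: multiplying all areas of a run by a
constant changes nothing downstream.

**Alignment.** Compounds are united across samples; a compound not
detected in a sample is recorded as 0, not missing. Zeros are
informative here — radiolytic hydrocarbons genuinely do not occur in
controls — so half-minimum-style imputation is wrong for these data and
is not offered.

## Design of experiments

The extraction optimization uses a face-centered central composite
design (axial distance α = 1), because the three levels of each factor
(temperature 30/40/50 °C, time 20/40/60 min) coincide at the factorial
and axial points; with three center replicates this is the 11-run
layout. A full second-order polynomial (6 coefficients for k = 2) is fit
by ordinary least squares in coded units, leaving 5 degrees of freedom —
the standard response-surface model family for a CCD. Each response is
mapped to a larger-is-better Derringer desirability with bounds
defaulting to the fitted surface's own min/max over the design domain
and exponent s = 1, so d spans [0, 1] on the explored region; the
global desirability is the geometric mean, which gives any response a
veto (d_i = 0 ⇒ D = 0). D is maximized by exhaustive evaluation on a
regular grid (default 201 × 201): the domain is two-dimensional and
tiny, and a deterministic scan with first-in-row-major tie-breaking
(ties are flagged) is worth more than a faster local optimizer.
Fiber coatings are compared on the VOC-count response with a dominance
rule: a fiber that is at least as good on every run wins outright;
otherwise the higher mean wins with a non-dominance flag.

## Chemometrics

**Scaling.** Autoscaling (column mean-centering and unit variance,
n − 1 denominators throughout) is the default for GC–MS normalized
areas, which span orders of magnitude between compound classes.
Constant columns are centered and left at zero with a warning. Inside
any cross-validation, scaling is refit on the training partition only.

**PCA** is computed by SVD of the scaled matrix; explained fractions are
σ_i²/Σσ_j² over all singular values; component signs are fixed by making
each component's largest-magnitude loading positive so score plots are
reproducible. Group confidence ellipses in the PC1/PC2 plane use the
group mean and covariance scaled by the χ² quantile with 2 degrees of
freedom (5.991 at the 95 % level).

**PLS-DA.** A single NIPALS PLS2 model regresses the autoscaled X on
the centered one-hot class indicator matrix; the inner NIPALS loop stops
when the weight vector changes by less than 1e-10 or after 500
iterations. Continuous predictions are the fitted class indicators.
Hard class assignment uses the Mahalanobis distance to each class
centroid in latent-score space under the pooled within-class score
covariance (Euclidean centroid distance and the raw indicator
arg-max/0.5-threshold rule are available as alternatives). The
distance rule is deliberate: least-squares indicator regression is known
to *mask* classes whose mean lies between other class means — here the
intermediate doses sit between the control and the 6 kGy group along the
dose trajectory, and with arg-max prediction their recovery saturates
around 85–93 % no matter how separated the groups are, while the
distance rules classify essentially perfectly on the same fitted model.
Distance-based prediction is also what the widely used chemometric
PLS-DA implementations do. For the panel's AUROC, the per-class ranking
score is the negative class distance — the score the classifier actually
ranks by; RMSECV, Q² and DQ² are computed on the continuous indicator
predictions, as their definitions require.

**VIP.** Variable importance in projection follows the standard
formula with per-component explained-Y sums of squares
SSY_a = ‖q_a‖²·t_aᵀt_a; mean VIP² = 1 on every fitted model. Markers
are variables with VIP ≥ 1.2 (boundary inclusive), either from the
global model or per class (each class weighting SSY by its own
indicator loadings); the pipeline reports the union of per-class
selections, mirroring how published marker lists pool class contrasts.

## Validation

**Double cross-validation.** The outer loop (default 5-fold stratified,
20 repetitions; the heavier analyses in the test suite use 5
repetitions) estimates held-out performance; for each outer fold an
inner stratified CV (default 5-fold) on the outer-training set alone
picks the latent-variable count (1..max, default 5) maximizing pooled
inner Q²; the model and its scaler are then refit on the outer-training
set and applied to the held-out fold. Per-class diagnostics come from
the pooled outer predictions of each repetition and are aggregated as
mean and median across repetitions. No held-out sample influences
scaling, complexity selection or fitting for its own fold; the test
suite checks this with a column that is informative only on the
held-out fold.

**Diagnostic panel.** Efficiency is the geometric mean of sensitivity
and specificity; precision TP/(TP+FP); Matthews correlation uses all
four confusion cells. Undefined ratios (zero denominators) are reported
as missing, never as 0. DQ² is the discriminant Q²: residuals of
predictions beyond their class label (ŷ > 1 for class 1, ŷ < 0 for
class 0) are zeroed, since overshooting the correct side of the
boundary is not a classification error; DQ² ≥ Q² always. AUROC is the
Mann–Whitney concordance probability with ties counted ½.

**Permutation test.** Labels are permuted uniformly; each iteration
re-runs a stratified k-fold cross-validated PLS-DA — at a fixed
latent-variable count (default 2) rather than a full nested selection,
a tractability compromise since the null does not reward complexity
tuning — and records the misclassified count. The exact
Binomial(n, 0.5) mass function is attached as the no-structure
reference, and the unpermuted model's count gets the left-tail
(b + 1)/(m + 1) empirical p-value, which can never be exactly zero. The
default is 1,000 iterations (the validation scripts use 500); the
30,000 used in large studies is configurable.

## The synthetic study

Real chromatograms for such irradiation studies are rarely deposited,
so the generator emulates the study conditions: per cheese 45
non-irradiated samples plus 15 at each of 2.0, 4.0 and 6.0 kGy; 63
(Brie) or 79 (Camembert) VOCs partitioned into 12 chemical classes with
the published class compositions. Class dose-response templates encode
the qualitative radiation chemistry:

* alkanes, alkenes, alkynes (radiolytic hydrocarbons), aldehydes and
  terpenes increase monotonically with dose (linear in dose);
* alcohols, carboxylic acids, esters, methyl esters, ketones, lactones,
  sulfur compounds and aromatics peak at 4.0 kGy (quadratic in dose
  with vertex at 4.0 — the simplest shape with that property);
* packaging/processing contaminants ("other") are flat.

Radiolytic hydrocarbons are exact structural zeros at dose 0, except
one configurable alkane that mimics n-hexane's presence in untreated
samples. Only a subset of each responsive class carries the dose effect
(counts mirroring the per-class composition of published marker lists,
~22–24 discriminant VOCs per cheese); the rest stay flat at their base
level, since published VIP selections cover only ~15 of 63–79 VOCs.
Noise is multiplicative log-normal (areas are positive, chromatographic
variance is multiplicative, and zeros stay exactly zero), with
σ = 0.25 on the log scale (≈ 25 % CV) and a 3× fold-change at each
template's maximum as defaults — effect sizes at which near-perfect
double-CV discrimination is attainable, as in the best published
surface-ripened-cheese panels, while the noise level is conservative
for replicate analyses of homogenized aliquots.

What the synthetic data do **not** emulate: retention-time drift and
co-elution, censoring at the detection limit, correlated noise between
compounds sharing a pathway, batch effects across measurement days, and
biological (between-cheese-wheel) variability — the 15 per-dose
replicates of the emulated design are technical replicates of one
homogenized sample, and the generator inherits that optimism. Passing
tests therefore demonstrate the correctness and internal consistency of
the algorithms, and that the workflow recovers planted structure at
realistic signal-to-noise; they do not certify performance on data with
the artifacts above.

## Numerical conventions and edge cases

* Variance uses n − 1 denominators everywhere.
* PLS component extraction stops early when X or the X–Y covariance is
  exhausted; a model that explains no Y variance has undefined VIP and
  raises.
* Singular or rank-deficient OLS model matrices raise rather than
  pseudo-inverting; PCA requests beyond the matrix rank truncate with a
  warning.
* Degenerate group covariances make confidence ellipses an error, not a
  degenerate plot.
* All stochastic procedures take explicit seeds; identical seeds and
  configurations reproduce outputs byte-for-byte.

## Problem sizes used in the shipped analyses

The acceptance script runs the permutation null at 500 iterations on a
90 × 30 null table; the test suite's double-CV analyses run 5
repetitions of 5 × 5-fold nested CV on the 90 × 79 Camembert table.
Both finish in seconds on one CPU; the defaults (20 repetitions, 1,000
permutations) and the publication-scale 30,000 permutations scale
linearly.
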