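# Methods

This note documents the models, defaults and numerical choices behind
`toxclass`, and what the synthetic-data tests do and do not demonstrate.

## Data model

All stages exchange probe-set × sample matrices of log2 intensities
(`ExpressionMatrix`) or treated-minus-control log2 differences
(`ContrastMatrix`). The package deliberately starts *after* normalization:
raw array processing (background correction, quantile normalization,
probe summarization) is heterogeneous across platforms and labs, and the
analysis itself only assumes a complete, normalized log2 matrix. Missing
values are rejected rather than imputed; order of probes and samples is
preserved from the input, and every join is by identifier.

The design table records, per treated sample, 1–2 matched control arrays
from the same experiment. The contrast for a treated sample is its column
minus the mean of its matched controls; control columns are dropped. This
paired subtraction removes additive per-experiment offsets exactly, which
is why the classifier and all downstream statistics operate on contrasts
without any further batch correction — the location/scale adjustment
below is provided for comparison views of absolute expression, not as a
pipeline stage.

## Batch adjustment (ComBat model)

`combat_adjust` implements the parametric empirical-Bayes location/scale
model: per probe, data are standardized by a linear model with per-batch
intercepts and (by default) a treated/control covariate so treatment
signal is not absorbed into batch terms; per-batch location γ̂ and scale
δ̂² are estimated on the standardized scale and shrunk toward a normal /
inverse-gamma prior whose hyperparameters come from method-of-moments fits
across probes. The conditional updates for (γ*, δ*²) are iterated to a
relative change below 1e-4. `parametric=False` skips shrinkage and reduces
to direct per-batch standardization, which is what the unit tests compare
against an independent per-cell oracle. Batches with fewer than two
samples are rejected (scale not estimable).

## Moderated t and consensus genes

Each compound is tested with a one-sample t of its mean contrast against
zero. Variances are moderated: with d_g = n−1 residual degrees of freedom
and per-probe sample variance s²_g, the posterior variance is
s̃² = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and t = mean/(s̃/√n) with d₀ + d_g
degrees of freedom. The prior (d₀, s₀²) is fitted per compound by moment
matching on the log-variance scale: the excess of the observed variance of
log s²_g over the sampling term trigamma(d_g/2) determines d₀ through a
Newton inversion of the trigamma function. When the observed spread does
not exceed the sampling spread the fit returns d₀ = ∞ and the test
degenerates to a z-test against the pooled prior variance — the correct
limit for homoskedastic data. `prior_df=0` forces the ordinary t, which
the tests use as an oracle equivalence.

Significance: linear |fold change| > 1.5 **and** BH-adjusted p < 0.05,
both strict inequalities; the fold-change rule is applied to the magnitude
in either direction. A gene is deregulated when at least one of its
annotated probe sets is significant; when significant probes of one gene
disagree in direction, the probe with the smallest adjusted p wins (ties:
larger |FC|, then probe id) — a deterministic rule chosen because the
underlying convention is not fixed by the field. Consensus sets collect
genes deregulated in the same direction by at least m = 4 compounds of a
class; m is a parameter and the same default applies to both classes.

## Classifier

The classifier is a linear soft-margin SVM (libsvm via scikit-learn,
solver tolerance 1e-7) on contrast-space feature vectors. Per training
split: (1) the 100 highest-variance probe sets within the training columns
are selected (unbiased n−1 variance; probes constant in training are never
selected even if globally variable); (2) the cost C is tuned over
2⁻⁵ … 2² by seeded stratified cross-validation (10 folds, capped at the
smaller class size), ties resolved toward the smallest C; (3) the SVM is
fitted; (4) class probabilities are calibrated by a one-dimensional
logistic fit along the decision axis, p = 1/(1+exp(A·f + B)), by penalized
maximum likelihood with the standard smoothed targets
t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2), which keeps (A, B) finite on separable
data (Newton iterations with backtracking line search).

Validation is compound-level leave-n-out: all C(M, n) subsets of the M
compounds are enumerated lexicographically; each split rebuilds the full
pipeline (feature selection, tuning, fit, calibration) on the remaining
compounds and predicts every replicate of the left-out compounds. A
compound is called class A when its mean replicate probability exceeds
0.5; a mean of exactly 0.5 is counted as unclassified and incorrect, since
the call rule is strict. Tuning seeds per split derive deterministically
from the run seed. Compounds with five replicates contribute all five to
training and prediction.

Panel minimization fixes the start panel once, from the variance ranking
over *all* treated columns, and removes one probe (the lowest-variance
member) per step; each size is revalidated with the panel held fixed in
place of per-split feature selection. Because the start panel sees all
compounds, this stage — unlike plain leave-n-out — carries a mild
selection leak; that is the procedure being modelled, and the leak-free
alternative is simply `leave_n_out` with default feature selection. The
predictivity curve need not be monotone in panel size: each probe's weight
depends on all other probes in the respective classifier.

## TF co-expression network

Mutual information between expression profiles is estimated with the
Kraskov kNN estimator (variant 1): Chebyshev-norm distances to the k-th
neighbour (k = 9), marginal neighbour counts with strict inequality, and
the digamma correction ψ(k) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩. A seeded
jitter of amplitude 1e-10 breaks ties from quantized intensities; negative
estimates are floored at zero. The CLR transform standardizes each MI
value against its two row backgrounds, z_i(j) = max(0, (MI_ij − μ_i)/σ_i),
combined as √(z_i² + z_j²); rows with zero spread contribute nothing.
Edges are the top 0.1 % of upper-triangle scores among transcription-
factor nodes — the cut point is the (1 − retention) empirical quantile
with linear interpolation, and ties at the threshold are all kept, so the
retained count is deterministic given the scores. Communities come from
greedy modularity agglomeration (networkx), with the largest 18 flagged
for enrichment; enrichment per (gene set, community) is the one-sided
hypergeometric tail with the network nodes as universe. Node placement is
a seeded Fruchterman–Reingold layout whose area parameter sets the side
length of the drawing region; a single node sits at the origin. The
curatorial naming of communities from enrichment tables is intentionally
left to the analyst.

## Synthetic data

The generator emulates the statistical structure of a two-class, twelve-
compound microarray study: 10,000 probe sets mapped many-to-one onto
8,000 gene symbols (10 % unannotated), 35 controls, two measurement
batches with per-probe additive offsets (SD 0.5 log2 units) and noise
scale factors (0.8–1.25), Gaussian replicate noise of SD 0.5 log2 units,
and baselines uniform on 4–12 log2 units. Treated samples add a
class-shared signature (300 probes per class, magnitudes uniform on
1.5–2.5 log2 units, signs random) that each compound expresses with
probability 0.8 — so the ≥4-of-6 consensus rule is non-trivial — plus
compound-private signatures whose sizes (100–3,000 probes) span the order
of magnitude of heterogeneity seen in real per-compound DEG counts, with
Gamma(2)-distributed magnitudes so that many private effects sit below the
detection threshold. The shared-effect magnitude floor of 1.5 was chosen
from a power calculation: with four replicates, noise SD 0.5 and paired
controls, per-compound detection of a 1.5 log2-unit effect at FDR 0.05
exceeds 95 %, which is what makes class signatures reliably recoverable
by the consensus rule. Batch assignment is stratified so every compound
and the controls span both batches.

What the generator does **not** model: probe-level hybridization
artifacts, intensity-dependent variance, correlated noise between probes
of one gene, or compound-specific dose structure. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under its stated assumptions, not performance on any particular real
dataset.

The co-expression generator is a single-factor model per module: gene
x = λ·f + √(1−λ²)·ε with a shared standard-normal factor f, so the
expected within-module Pearson correlation is λ², which the tests check
in closed form.

## Problem sizes and numerical choices

The default study shape (12 compounds, ≤ 5 replicates, 10,000 probes) runs
each leave-one-out validation in a few seconds; test fixtures use smaller
probe counts where the property under test does not depend on scale.
Acceptance-level runs use the full default shape. Sign conventions:
decision values are oriented so positive means class A, and PCA component
signs are fixed by making each component's largest-magnitude loading
positive. Variance ties in feature ranking break lexicographically by
probe id; C ties break toward smaller C; community ids order by
decreasing size. All stochastic steps (generator, fold assignment, MI
jitter, layout) are seeded, and one run seed fans out to per-stage seeds
via `numpy.random.SeedSequence` spawn keys.

## Known limitations

- The leave-n-out scheme refits the C grid inside every split; with very
  few replicates the inner cross-validation is coarse (folds capped at the
  smaller class size).
- The panel-minimization start ordering is computed on the full data set
  (see above); interpret its curve as describing that specific procedure.
- The MI estimator's small positive bias at n = 1000, k = 9 (a few
  hundredths of a nat for strongly dependent Gaussians) is inherent to the
  kNN estimator and not corrected.
- `combat_adjust` implements only the parametric shrinkage variant; the
  non-parametric empirical-Bayes variant is out of scope.
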