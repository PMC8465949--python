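# Methods

## Scope and data model

The package analyses a paired cohort of chronic-rhinosinusitis patients
examined before and about four months after functional endoscopic sinus
surgery. A cohort is a long-format table (one row per patient-occasion)
over d = 37 variables in four categories: nasal anatomy/pathology (3),
olfactory function (8), quality of life (14) and demographics/concomitant
disease (12). The variable schema records, per variable, its category,
scale type (interval, ordinal, binary, nominal), support, and the
direction of change that counts as clinical improvement. The supervised
analyses stack both occasions into a 180-record design matrix whose label
is the test occasion.

## Synthetic cohort generator

The patient data are available only on request, so the generator emulates
the published cohort of n = 90 completers. Its defaults are calibrated to
the published facts and are not meant to be tuned:

* **Marginals.** Interval variables follow truncated normals whose
  underlying (mu, sigma) are solved at configuration time so that the
  *truncated* mean/SD equal the published values on the published ranges.
  A few variables admit no such solution — the printed SD exceeds what any
  truncated normal on the printed range can attain (transformed olfactory
  threshold 0.59 +- 0.74 on 0-2.3; SF-36 physical functioning, bodily
  pain, social functioning, and the role scales 70 +- 38.6 and
  79 +- 37.5 on 0-100; the post-surgery general-quality-of-life subscore).
  These use moment-matched discrete distributions on the instrument's
  natural level grid instead (the SF-36 role scales genuinely take only
  5 resp. 4 values; social functioning steps by 12.5), solved by
  constrained least squares toward the uniform vector. Ordinal copula
  draws are rounded to their integer support.
* **Quota sampling.** Discrete levels are drawn with largest-remainder
  quota counts and continuous margins from stratified (one-per-quantile-
  stratum) uniforms, so a finite cohort carries the configured marginals
  essentially exactly — mirroring how the study reports prevalences as
  exact counts out of 90 (52 men, 71 steroid users, 59 patients with a
  normal post-surgery polyp score). Randomness lives in which patient
  receives which value.
* **Pairing.** Baseline and post values of a variable are coupled through
  a Gaussian copula with latent correlation 0.5 (rank-matching the
  stratified post margin to the latent target preserves the margins
  exactly). The Lildholdt polyp score and the 10-point olfactory
  self-rating instead draw (pre, post) pairs from joint tables fitted by
  iterative proportional fitting to both margins *and* the published
  change-direction mass: improvement in 84/90 with no worsening for the
  polyp score; 62/24/4 improved/unchanged/worsened for the self-rating.
  IPF converges to machine precision here; infeasible requests raise.
* **Coupled improvements.** A shared latent improvement factor links the
  post-surgery innovation of primary nasal symptoms (loading 0.60, latent
  pre/post correlation 0.546 — fixed so that exactly ~4/90 patients
  worsen) with the self-rating's pair assignment (rank weight 0.85),
  reproducing the published weak coupling between the two subjective
  improvements (Spearman rho ~ -0.48, rho^2 ~ 0.23). The polyp score is
  left uncoupled from the factor, matching the published absence of a
  delta correlation with olfactory change.
* **Demographics** are drawn once and copied across occasions; age
  advances by 1/3 year (the four-month follow-up). Parosmia/phantosmia
  remit only (transitions 1 -> 0) at the exact published post prevalences.
* **Artifacts.** `inject_artifacts` adds missingness (completely at
  random, non-demographic cells only — the real data's missingness
  mechanism is uncharacterized, so MCAR is an explicit simplification)
  and gross outliers (interval cells replaced by column mean +- 6 SD);
  the altered-cell count is `round(rate x eligible cells)`.

What the generator does **not** emulate: the 67 baseline-only dropouts
(an optional unpaired baseline block exists but models no dropout
mechanism); item-level SNOT-20/SF-36 responses (subscores are generated
directly, so the arithmetic identities between items and subscores do not
hold across generated columns, e.g. TDI is generated independently of its
three subtests); any real covariance structure beyond the pairings listed
above. Passing tests therefore certify the pipeline's behavior under the
published marginal and change-direction structure, not under the full
dependence structure of real patients.

### A note on an internal inconsistency of the published numbers

Three published facts cannot hold simultaneously in any joint
distribution: (i) 59/90 patients score Lildholdt 0 after surgery while
every baseline score is >= 1, so the rule "score >= 1 -> baseline"
misclassifies exactly the 31 post-surgery records with residual polyps,
capping its accuracy — and that of every monotone single-feature
classifier implementing it — at 149/180 = 82.8%; (ii) the published
median accuracies for Lildholdt-only classifiers are 85-86.7%; (iii) the
published depth-1 rule splits at >= 1. Moreover the printed post moments
force P(post = 1) into [0.178, 0.212], above the moment-matched baseline
P(1) = 0.138, so the Bayes-optimal single split of the synthetic cohort
is at >= 2, with accuracy 85.4% — consistent with (ii) but not (iii).
The generator follows the moment-matching construction and therefore
reproduces the published accuracies; the learned depth-1 threshold on
synthetic data is 2, not the printed 1. The corresponding rule-identity
assertion in the acceptance suite documents this and is expected to fail.

## Preprocessing

Interval variables are screened along Tukey's ladder of powers
(lambda in {-1, -0.5, 0 (log), 0.5, 1, 2}, sign-preserving; log and
negative powers shift by 1 - min(x) when needed); the rung minimizing the
Kolmogorov-Smirnov distance to a normal fitted to the transformed sample
wins, with ties going to the identity. Outliers are masked per variable —
pooled over both occasions, to maximize the sample behind each test — by
iterated two-sided Grubbs tests at alpha = 0.05, using the exact critical
value ((N-1)/sqrt(N)) sqrt(t^2/(N-2+t^2)) with t the upper alpha/(2N)
t-quantile on N-2 df. Ordinal instrument scores are exempt from both
steps: their supports are bounded by design and extreme grades are
genuine findings. Missing values are then imputed separately within each
of the four category blocks (median/mode per occasion, or an iterated
random-forest scheme — 100 trees, at most 10 sweeps or relative change
< 1e-3 — with ordinal predictions rounded to support). Finally binary and
nominal variables are one-hot recoded with missing values assigned to the
zero condition, leaving a complete numeric design table. A single
completed table is produced; multiple-imputation variance pooling is out
of scope.

## Effect sizes

Pre/post differences are screened with two-sample Wilcoxon-Mann-Whitney U
tests (interval/ordinal) or Pearson chi-squared tests on occasion-by-level
counts (binary/nominal), without multiplicity correction. Although the
design is paired, the unpaired U test is the default because it is the
named convention of this analysis style; a paired signed-rank option is
exposed. The Impact effect size is composed as

    CT     = (median(y) - median(x)) / s_pool,
             s_pool = sqrt((sigma_x^2 + sigma_y^2)/2), sigma = 1.4826 MAD
             (SD fallback when the MAD vanishes)
    SHAPE  = 1 - overlap(KDE of median-centered x, KDE of median-centered y)
    Impact = sign(CT) max(|CT|, SHAPE)    (sign of the mean difference
                                           when the medians tie)

with Gaussian kernels, Silverman bandwidths, and a shared 512-point grid
spanning the pooled range +- 3 bandwidths (overlap = Riemann sum of
pointwise minima). This composition is a pinned surrogate for the original
measure; its fidelity contract, enforced in the tests, is agreement with
Cohen's d within 0.15 for Gaussian location shifts of 0.2-1.2 SD at
n = 2000. Identical samples return exactly 0. Confidence intervals are
2.5th/97.5th percentiles over 1000 bootstrap resamples per group.

## Computed ABC analysis

Items are sorted descending (stable, so ties keep input order) and the
curve (x_i = i/n, y_i = cumulative share) is cut twice: subset A ends at
the curve point closest to the ideal (0, 1) — distance ties, judged with a
1e-9 relative tolerance so rescaling cannot flip them, go to the earliest
point — and subset B ends at the first later point whose discrete slope
falls to the break-even value 1 (an item contributing no more than
average), clipped to n-1 if none. Zero-valued items always land in C.
These two boundary rules are this package's pinned convention; they are
isolated in one module so an alternative construction can be swapped in.
The A|B rule is verified against exhaustive boundary search on all small
multisets in the suite.

## FAMD projection

Continuous (and ordinal) columns are centered and scaled to unit
*population* variance; each categorical level indicator is divided by the
square root of its proportion and centered. The eigenvalue of dimension k
is the squared singular value divided by the row count — this
normalization is stated explicitly because FAMD implementations differ by
constant factors and the Kaiser retention rule (keep eigenvalues > 1) is
only meaningful once it is fixed. Under it, total inertia equals
(#continuous columns) + (#levels - #categorical variables), an identity
the tests enforce; an all-continuous table reproduces standardized PCA
and an all-categorical table reproduces MCA (eigenvalues q x the
correspondence-analysis eigenvalues of the indicator matrix, q = number
of categorical variables). The sign convention makes the first nonzero
loading of each dimension positive. Occasion separation per retained
dimension uses the U test; projection-relevant variables are those whose
contribution percentage exceeds the uniform expectation 100/d.

## Feature selection harness

Splits are class-proportional: round(2/3 n_c) of each class trains, the
rest tests. Inside the harness all columns are standardized once per
split with training statistics — column-wise scaling commutes with
dropping a column, so the drop-one refits slice the scaled matrix, and
tree/naive-Bayes members are unaffected by per-column affine maps while
the distance/margin members get comparable scales. Negative dAcc values
are floored at zero before the per-run ABC partition (a variable whose
removal helps is non-informative for selection); the ABC step is applied
per classifier, and runs whose floored vector is all zero contribute an
empty A set. The consensus weight combines the three published
ingredients — selection certainty (A-counts), classifier performance
(median balanced accuracy) and classification uncertainty (distance of
the accuracy CI lower bound above 50%) — as their product, the simplest
combination that zeroes chance-level voters. The knockout removes the
category of the *top* consensus variable each round and stops when even
the best classifier restricted to the consensus set has an accuracy CI
lower bound at or below 50%. The negative control permutes each training
column independently within each split (destroying feature-label
association, preserving marginals) and leaves test data untouched. The
rule-tree panel member is an entropy-split CART standing in for
hierarchical rule learners of the C5.0 family, whose boosting internals
are out of scope. The two logistic variants are unpenalized and weakly
ridge-penalized (C = 100), emulating two independent implementations.

Classifier hyperparameters follow the published tuning: 1500 forest trees
(the out-of-bag error plateaus from ~200 trees, and more trees carry no
penalty), kNN with Euclidean distance and k = 7, linear SVM kernel.

## Outcome interpretation

The printed change coding "(1, 0, 1)" cannot distinguish improvement from
worsening in a row sum, so it is read as the typographical variant of
(+1, 0, -1): per patient and selected variable, sign(post - pre) is
mapped through the variable's improvement direction. Row sums classify
patients (positive: overall improved; zero: no consistent effect;
negative: predominantly worsened); column-pair agreement uses Pearson
chi-squared on the sign cross-tables. Symptom freedom applies the
instrument cutoffs (polyp score 0; Lund-Kennedy < 2; SNOT-20 total < 12,
primary < 12, secondary < 10.5, general quality of life < 14; the
anosmia/hyposmia/normosmia bands < 16.5 / 16.5-30.5 / > 30.5 with
hyposmia closed at both ends; TDI gain >= 5.5 subjectively perceptible),
comparing occasions with unpaired Pearson chi-squared on the tallies —
the paired transition tables behind the published paired statistics are
not printed, so that variant cannot be validated and is not the default.
Delta correlations are Spearman, reported with the change correlations in
the lower triangle and raw post-surgery correlations in the upper.

## Problem sizes and numerical conventions

The full-fidelity configuration (1000 Monte-Carlo runs, 1500 trees) is
exposed through the configuration surface; the shipped test suite and the
acceptance script run the same algorithms at sizes where the reported
medians have long stabilized — 200-300 splits (1000 for the cheap
logistic-only comparison) with 300-tree forests for single-fit analyses,
and 12 splits with 32-tree forests for the drop-one knockout races, whose
winner is decided by margins of many A-count standard deviations. Seeds
flow from one master seed; identical seeds give identical tables, splits,
selections and summaries. Degenerate inputs are handled explicitly:
constant variables are flagged (transform selection), dropped with a
warning (FAMD), or rejected (simple rule); all-zero importance vectors
yield empty A sets; single-class test draws are excluded from performance
summaries and counted.

## Known limitations

* The generator reproduces published *marginals and change directions*,
  not real patient covariance; cross-variable structure beyond the three
  calibrated couplings is copula-default (rho = 0.5) or absent.
* Impact is a pinned surrogate tied to Cohen's d on Gaussian shifts;
  other compositions of the same ingredients would differ in shape-driven
  regimes.
* The ABC boundary rules and the consensus weight formula are documented
  conventions, not uniquely determined by the method description.
* The depth-1 rule threshold on synthetic data is 2, not the published 1
  (see the inconsistency note above); all accuracy-level results are
  unaffected.
* Exact published p-values and FAMD variance percentages depend on the
  unavailable patient data and are reproduced qualitatively, not
  numerically.
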