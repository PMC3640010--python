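# Methods

This note documents the statistical models and procedures implemented in
`episelect`, the parameter defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Cohort model and imputation

A cohort is a table of n patients by p categorical features plus a complete
binary outcome derived from the Engel surgical-outcome scale: grade I
(seizure-free) versus grades II–III pooled (improvement without full
recovery). Grade IV never occurs in the target cohort and is rejected
rather than silently pooled. Every feature carries an ordered category
vocabulary; the order doubles as the ordinal coding for rank tests and as
the deterministic tie-break order everywhere a mode or winner must be
picked.

**Discretization.** Continuous clinical measurements map onto the study's
printed bins (surgery age 17–32/33–54; onset age 0–1/2–10/11–20; elapsed
time 7–13/14–19/20–39 years). Printed integer edges cannot literally cover
the observed values (onset ages 0.7 and 1.8, durations 4 and 40), so bin
boundaries sit at the lower printed edge of each bin after the first, with
the first bin open below and the last open above. Negative values raise
rather than clamp. Free-text seizure-frequency entries map onto the
six-category vocabulary by a documented table; entries without a single
weekly figure ("not regular", "0–3 weekly") fall into *Other*, and "3–5
weekly" takes its lower figure. This mapping is a package choice — the
original coding of these entries is not recorded.

**Imputation.** Missing cells are filled once, on the whole cohort, with
the most frequent observed category among patients of the same outcome
class; within-class ties break by vocabulary order, and a feature with no
observation in one class falls back to the overall mode with a warning.
Imputing before cross-validation reproduces the original workflow but
leaks outcome information into later CV estimates (the imputed cell is a
function of the patient's own class); the pipeline logs this, and
`loocv_evaluate(..., impute_in_folds=True)` provides the strict variant
that re-imputes inside every training fold, using training-fold overall
modes for the held-out case. Imputation is idempotent and never touches
observed cells, ids or outcomes.

## Classifiers and evaluation

All three paradigms consume integer-coded categories under the shared
schema; models validate that query cohorts carry the training vocabulary,
so a label can never be silently re-indexed.

- **Naive Bayes.** Class priors are unsmoothed relative frequencies;
  class-conditional category probabilities are Laplace-smoothed,
  P(x_j = c | y) = (n_{jc,y} + α)/(n_y + α·C_j) with α = 1 by default, so
  unseen categories keep positive mass. Folds that lose an entire class
  (impossible at the study's 14:5 composition, possible in degenerate
  inputs) fall back to smoothed priors with a warning.
- **Ridge logistic regression.** Full one-hot encoding of every category
  of every feature, unpenalized intercept, penalized log-likelihood
  ℓ(w) − (λ/2)‖w‖² maximized by damped Newton iterations to gradient norm
  1e-8 (max 200 iterations). λ defaults to 1e-8 — effectively unpenalized
  but numerically stabilized; at λ = 0 on separable data the fit returns a
  non-convergence flag instead of diverging. The one-hot redundancy
  direction is regularized away by the penalty, making the optimum unique;
  tests verify agreement with a generic BFGS optimizer on the same
  objective.
- **k-NN.** Overlap (Hamming) distance over the selected features, k = 3
  by default (odd, so vote ties cannot occur at complete data; exact
  distance ties break by original row order, residual vote ties toward the
  training majority class). The posterior is the vote fraction.

**LOOCV.** n fits, each leaving one patient out; accuracy is the mean 0/1
correctness of the held-out predictions. The ROC AUC is computed once from
the n pooled held-out scores (not averaged across folds — with one test
case per fold a per-fold ROC does not exist) using the Mann–Whitney
estimator with midrank tie handling, which tests verify against explicit
trapezoidal integration of the empirical ROC. F₁ uses seizure-free as the
positive class — the only convention simultaneously consistent with a
17/19 accuracy and F = 0.9333 on a 14:5 cohort. Naive Bayes LOOCV is
computed by subtracting each held-out row's contribution from the full
count tables, which is exactly equivalent to n refits (tested) and makes
the bootstrap race tractable.

## Feature selection

**Backward race.** Starting from all features, each lap evaluates every
single-deletion candidate by its per-fold LOOCV 0/1 error vector.
Candidates significantly worse than the incumbent under a paired t-test on
the fold errors (α = 0.05; an unpaired Welch variant is available) are
eliminated from the lap. Among the survivors the lowest-mean-error
candidate wins and replaces the incumbent when its mean error does not
exceed the incumbent's; the tie case favors the deletion, so features
whose removal costs nothing are pruned — under a strictly-lower rule the
search stalls immediately on clean data where error vectors tie, and no
selection pressure exists at all. Exact ties between equally good
deletions are broken uniformly by the seeded generator; a deterministic
first-in-name-order rule would systematically favor late-alphabet
features (this is measurable as a monotone trend in bootstrap counts).
The race stops when every deletion strictly degrades the mean error or
one feature remains; the result is never empty.

**Bootstrap stability ranking.** Because a single race on ~19 patients is
unstable, the race runs on B stratified bootstrap resamples (exactly the
original number of patients drawn with replacement from each outcome
class; duplicated rows count as distinct instances) and each feature is
ranked by how many selected subsets contain it. Resample r uses an RNG
stream derived from (seed, r), so results are reproducible and independent
of execution order. B = 1000 reproduces the study's scale; tests and the
acceptance harness use B in the tens-to-hundreds to keep runtimes in
seconds-to-minutes, which is a problem-size choice of this package.

**Incremental evaluation.** Ranking prefixes of sizes 1…p are each scored
by LOOCV; the best point maximizes accuracy, with ties resolved toward the
smaller subset and then the higher AUC. A caveat this package documents
deliberately: on cohorts where naive Bayes is insensitive to extra
class-independent features, the accuracy curve plateaus after the
informative prefix and the argmax rule then picks chance peaks at larger
sizes; k-NN, whose accuracy genuinely degrades as noise dilutes the
overlap distance, yields a peaked curve. The argmax-with-ties rule is kept
because it mirrors the original subset choice; consumers who need
parsimony under a plateau should inspect the whole curve.

## Exact rank tests

Ordinal codes follow vocabulary order (Low < Normal-Low < Normal <
Normal-High < High; EB1 < EB2 < EB3; Left < Right; Negative < Positive).
The two-sample comparison grouped by outcome is a Wilcoxon rank-sum test
made exact under ties: pooled midranks, then the null distribution of the
smaller group's rank sum over all C(n, n₁) assignments by dynamic
programming over doubled (integer) midranks; the two-sided p doubles the
smaller tail including the observed value, capped at 1. The exact path
covers n ≤ 25 (the study regime); larger samples use the tie-corrected
normal approximation. The signed-rank test for paired pre/post differences
discards zeros (Wilcoxon's original treatment), midranks |Δ| ties, and
enumerates all 2^m sign assignments for m ≤ 20, with the same two-sided
convention. Tests verify both against brute-force enumeration, against
classical no-tie distributions, and for invariance under monotone
recoding. No multiplicity correction is applied by default, matching the
original 19-test table; Bonferroni/Holm are available.

The per-feature test table can also be grouped by any binary vector — in
particular a cluster assignment — which reproduces the post-surgery
cluster-difference comparisons.

## Multinomial-mixture clustering

The latent-class model: each patient belongs to one of K components with
probability w_k; given the component, features are independent categorical
draws from per-component tables θ_{kj}. EM with soft responsibilities runs
to a relative log-likelihood change below 1e-8 (max 500 iterations), best
of 10 restarts initialized from symmetric-Dirichlet responsibilities.
M-step category counts receive 1e-6 pseudo-mass so no probability locks at
exactly zero; the smoothing is far below one observation, and the
log-likelihood trace is verified non-decreasing (tolerance 1e-10) on every
fit. Components collapsing below weight 1e-6 warn. Agreement scoring
hard-assigns each case to its argmax responsibility (an exact 0.5 tie goes
to component 0 and is flagged), picks the component-to-label mapping with
the most matches, and reports the mismatched case ids — applied to the
published 15-case membership table this yields 13/15 correct with an
8-case all-seizure-free cluster.

## Synthetic cohorts

The generator draws the outcome from a 14/19 seizure-free prior, the three
planted features (Side, P.Style, PIQ) from class-conditional tables equal
to the class-stratified contingencies derivable for the 19-patient
analysis cohort, the 16 remaining features class-independently from the
observed marginal counts, and missingness completely at random at the
per-feature study rates (up to 7/19 for the Rorschach indices). At n = 19
this reproduces the study's regime of high but not deterministic
separability. What it does **not** emulate: correlations among features
beyond their dependence on the outcome, any informative-missingness
mechanism, and the unpublished joint distribution of the real
neuropsychological profiles — so passing recovery tests demonstrates that
the pipeline finds planted class-dependent structure under realistic
marginals, not that it would reproduce the original cohort's exact
selections. Note also that class-conditional imputation of a
high-missingness class-independent feature makes the imputed cells
outcome-informative; this leak is a property of the imputation design, and
the generator makes it observable.

The recovery harness reruns the full pipeline (generate → impute → rank by
bootstrap frequency → incremental curve) over replicates and reports the
fraction in which every planted feature outranks every noise feature and
the fraction in which the best subset stays within planted ∪ one noise
feature. A separate separable two-component mixture generator (dominant
category probability 0.95, the two components disagreeing everywhere)
provides the clustering parameter-recovery check: at n = 300 the remaining
estimation error is multinomial sampling noise of order 0.02–0.04 total
variation per category table.

## Numerical and reproducibility choices

- All stochastic stages take explicit integer seeds; nested stages derive
  per-unit streams from (seed, index) so partial parallelism cannot change
  results. The pipeline manifest records every seed and rerunning a config
  reproduces all JSON artifacts byte-for-byte.
- Rank-sum/signed-rank exact distributions use doubled midranks to stay in
  integer arithmetic; probabilities come from exact tail sums, never
  simulation.
- Posterior computations run in log space with max-subtraction;
  responsibilities and posteriors sum to 1 within 1e-12.
- Degenerate inputs (constant outcome, empty groups, K > n, k ≥ fold size,
  all-zero confusion) raise informative errors rather than returning
  conventions, with the two documented exceptions: all-zero signed-rank
  deltas give p = 1 with m = 0, and zero-recall F₁ is 0.

## Known limitations

- The real per-patient neuropsychological table is unpublished; the
  19-feature classification stage therefore has no ground-truth fixture
  and its published headline metrics are not reproduction targets. The
  three-feature contingency reconstruction does reproduce the published
  LOOCV accuracy and F-measure under naive Bayes, but its joint feature
  arrangement is arbitrary, so its AUC is not comparable.
- Which 4 of the 23 patients lacked behavioral testing is underdetermined
  (constraints: all female, three Engel-I and one Engel-II/III); the
  packaged clinical table ships all 23 with the flag column unknown.
- The original racing configuration (test level, lap schedule) is uncited;
  bootstrap frequency counts are therefore qualitative shape targets, not
  numeric ones.
- The published k-NN F-measure (0.9035) is inconsistent with every
  17-correct-of-19 confusion matrix under standard per-class or weighted
  F definitions; it is documented, not reproduced.
- The published PIQ stratified percentages (73.7/26.3) equal 14/19 and
  5/19 rather than proportions within the PIQ-Normal row; the contingency
  adopted here is the one that reproduces the published exact p-value
  (0.0492) and the post-imputation marginals.
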