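# Methods

## Setting and model

The package implements the inference chain of a case/control expression
profiling study of histologically normal breast epithelium (NlEpi). Three
groups of microdissected samples are compared on probe-set level microarray
intensities (MAS5-style condensed, linear scale): RM (reduction mammoplasty,
usual-risk controls), HN (histologically normal epithelium from breasts
harbouring a cancer), and PM (cancer-free prophylactic mastectomy tissue from
high-risk women). The primary contrast is RM vs HN; the PM group is then
interrogated against the RM–HN signature by clustering; selected genes are
validated by relative-quantification qPCR.

## Preprocessing

Two steps only, matching the minimal treatment appropriate to condensed chip
output: (1) each sample column is rescaled by a scalar so its mean intensity
equals a target (default 200); (2) probe sets with fewer than 20% Present
detection calls across samples are removed (strict `<`, so a probe at exactly
the threshold is retained). Marginal calls count as *not* detected by
default — the conservative reading of P/M/A semantics — switchable with
`marginal_counts_as_detected`. No background correction or quantile/loess
normalisation is applied. Rescaling precedes filtering (the filter ignores
intensities, so only the retained matrix's scale depends on the order).

## Differential-expression scoring

Each probe set is scored by Bayesian model averaging over two positive,
right-skewed families fitted independently per group:

* **Lognormal.** Conjugate normal-inverse-gamma model on log intensities:
  `mu, sigma^2 ~ NIG(m0, kappa0, a0, b0)`. Hyperparameters: `m0` = pooled
  log-mean of both groups, `kappa0 = 0.1` effective observations, `a0 = 0.5`,
  and `b0 = 0.5 x` the pooled log-variance. Anchoring `b0` to the pooled
  variance (rather than an absolute constant) keeps the variance prior weakly
  informative *on the data's own scale*; an absolute scale lets the intensity
  unit decide the family weights, which is not a property a model average
  should have. Posterior draws are closed-form; the group mean on the linear
  scale is `exp(mu + sigma^2/2)`.
* **Gamma.** Laplace approximation around the MLE in `(log k, log theta)`
  (Minka-initialised Newton for the shape; the observed-information
  covariance has the closed form `(-H)^{-1}` with
  `H = -n[[k^2 psi'(k), k], [k, k]]`), corrected by importance-weighting the
  Laplace draws against the exact posterior. Priors are independent normals
  on `(log k, log theta)` centred on the pooled two-group MLE with sd 2 —
  the same empirical-Bayes anchoring as the lognormal family, chosen so the
  two evidences carry comparable prior penalties.

Family weights are proportional to the marginal likelihood of both groups
under the family (the lognormal evidence includes the `-sum(log x)` Jacobian
so both are densities over raw intensities; the gamma evidence is the
Laplace estimate). On lognormal-generated data (cv 0.2, 18 + 18 samples) the
lognormal family wins the weight for essentially every probe; the gamma
family overtakes it as skew grows (about 90% of probes for exponential
data). At these sample sizes the families are genuinely hard to tell apart
near cv 0.2, and the fold inference is nearly identical under either, so the
average is insensitive to the split.

Draws of the fold `mean_1/mean_2` from each family are pooled with model
weights (and, within the gamma family, importance weights). The directional
probability `p_greater = P(fold > 1 | data)` is the weighted fraction of
draws above 1; the **probability score** (the method's p-value) is
`1 - max(p_greater, 1 - p_greater)`, which lies in [0, 0.5]; the fold point
estimate is the weighted posterior median (robust to the ratio's right
skew). Exact reproduction of the original software's numeric output is not
claimed — orientation and approximate magnitude are.

Per-probe Monte-Carlo seeds are derived by hashing the global seed with the
probe id, so a probe's score does not depend on probe order or on which
other probes share the matrix (verified by a sub-matrix equality test).
Intensities at or below zero are floored at `epsilon = 1.0` before logs
(condensed matrices occasionally contain zeros).

For robustness reporting, the classical equal-variance t-test on natural-log
intensities and the plain ratio of group means accompany each probe.

## Stability selection

The scorer is sensitive but unspecific at n = 18 + 18, so selection is
wrapped in leave-one-out cross-validation: one run per left-out sample
(36 runs for the study design; a paired mode removing one age-matched sample
from each group is available), each run applying Benjamini–Hochberg step-up
to the probability scores and selecting adjusted values strictly below the
FDR threshold (default 0.06). Probes selected in at least 80% of runs
(`>=`, matching "at least 80% of the time") form the signature; final scores
and t-test p-values are recomputed once on all samples. The wrapper's value
is measurable on synthetic data: at 2,000 probes with 50 planted 3-fold
effects (cv 0.2), the wrapped selection attains sensitivity 1.0 with ~4
false positives where the single-pass selection admits roughly twice as
many. The FDR procedure is not named in the source study; BH is used because
it is standard and monotone.

## Cluster concordance test

Samples are clustered agglomeratively on the signature probes using
Euclidean distance between `log2(intensity + 1)` profiles and average
linkage (both switchable: correlation distance, complete linkage). The
transform prevents the brightest probes from dominating linear-scale
distances. The agglomeration is written in-house so tie-breaking is part of
the contract — equal minimum distances merge the lexicographically smallest
cluster-id pair — and coincides with the standard implementations on
tie-free input (tested against an independent implementation).

Removing the final merge yields a two-way partition. The "cluster result"
for a focal group is the count vector of its samples across (the block
holding the anchor group's majority, the other block) — e.g. how many PM
samples sit in the HN-majority block. The Monte-Carlo test permutes the
label vector uniformly (the identity permutation is not excluded) and counts
permutations whose pattern equals the observed one; since label permutation
cannot change sample distances, the tree is computed exactly once. A
`mode="at-least"` variant counts patterns at least as concordant in the
observed direction, giving a conservative p-value-like frequency. On a
balanced 4 + 4 design with perfect separation, the exact match probability
is 2/C(8,4) = 1/35 by enumeration, and the empirical frequency converges to
it (tested at 100,000 permutations).

Spearman rank correlation (mid-ranked ties) compares fold-change vectors
across contrasts; on the packaged signature table the RM:HN vs RM:PM fold
correlation is ~0.81.

## qPCR validation

Conventions are stated because the sign mapping is easy to invert: lower CT
means more template; `dCT = CT(test gene) - CT(reference gene)` per sample,
so lower dCT means higher expression; `ddCT = mean dCT(test group) - mean
dCT(reference group)`; the group fold is `2^-ddCT` (amplification efficiency
exactly 2, the method's assumption — no efficiency correction). A microarray
fold > 1 in reference:test orientation predicts that a test sample's dCT
exceeds the reference-group mean dCT; a reaction validates when it falls on
that side, and an exact tie counts as *not* validated (strict reading of
"in the predicted direction"). Group comparisons use the one-tailed
two-sample equal-variance t-test with the tail chosen by the prediction;
SEM = sd/sqrt(n). Missing reactions are simply absent rows; samples lacking
a reference-gene CT are excluded with a warning.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the biology of any particular chip:

* intensities are lognormal per probe/group (switchable to gamma — the two
  families the scorer averages over, so tests can probe mis-specification),
  with per-probe baselines `log-mean ~ N(5.0, 1.2^2)` and a within-group
  coefficient of variation `cv` (default 0.2 — the source data's
  within-group variance is uncharacterised, so this is a modelling choice of
  a typical condensed-chip value, fixed once);
* group sizes default to the study design (18 RM, 18 HN, 6 PM), with 98
  planted differential probe sets, fold changes log-uniform on [2, 6] and
  two thirds oriented higher-in-RM (the observed direction split);
  `pm_mimics_hn` makes PM copy the HN side of each contrast so RM:PM folds
  equal RM:HN folds;
* detection calls are independent Bernoulli (Present-probability 0.9 for
  expressed probes, 0.05 for the ~42% of probes marked unexpressed); an
  `intensity-linked` mode additionally forces the dimmest decile of each
  sample to Absent. No detection model is given by the source study; the
  independent default keeps the filter test interpretable;
* intensities are emitted unscaled — rescaling to mean 200 is the
  pipeline's job, as with raw condensed output;
* one seed drives a splittable generator with a stream per stage, so runs
  are bit-reproducible;
* CT tables are constructed so group dCT gaps encode planted folds exactly:
  per-sample loading offsets cancel in dCT, and Gaussian noise of sd
  `efficiency_noise_sd` perturbs each test-gene CT, making the per-reaction
  dCT noise sd equal to that parameter.

What the generator does **not** emulate: probe-level cross-hybridisation,
chip spatial artefacts, correlated probes within a transcript, batch
effects, or intensity-dependent variance beyond the constant-cv families.
Passing tests therefore demonstrate that the inference chain recovers the
structure it assumes, not that it is robust to everything real chips do.

## Numerical choices and degenerate inputs

Constant groups: the gamma shape MLE is capped at 1e8; a zero pooled
variance makes the t-tests return NaN as an "undefined" flag. Groups of
fewer than two samples are rejected (variance undefined); the LOO wrapper
requires at least three per group so every removal leaves two. Weighted
medians resolve at the first draw whose cumulative weight crosses one half.
BH uses the standard step-up adjustment with strict `<` at the threshold.
Tie-breaks in clustering and anchor-majority ties in the concordance pattern
(resolved toward the block containing the first-listed anchor sample) are
deterministic and documented.

## Operating characteristics and problem sizes

The shipped checks use: 2,000 probes (50 planted 3-fold) with 2,000
posterior draws per family for the selection operating characteristics;
100,000 permutations for the enumeration-oracle comparison; 10,000
permutations for the study-sized three-group clustering run; 2,000-replicate
Monte-Carlo bands (frozen in the tests) for the qPCR estimators. Posterior
draws below the default 10,000 are used only where the assertions concern
quantities far from decision boundaries.

One calibration fact worth stating plainly: because the probability score is
`1 - max` of a directional posterior probability, it lives on [0, 0.5], and
for a *calibrated* scorer the null fraction of scores below 0.05 is ~0.10
(both directional tails), not 0.05. The scorer here is near-calibrated (KS
statistic of the doubled score against uniform ~0.02 on 2,000 null probes),
and the measured null fraction is ~0.09–0.10. Any scorer reporting ~0.05
for this quantity is either miscalibrated by deliberate shrinkage or is
reporting a different (two-sided-style) score.

## Known limitations

* The original scoring software's exact families, priors, and estimator are
  not public through this study; this implementation fixes its own
  documented priors, so per-probe folds and scores match the printed
  signature in orientation and rough magnitude only.
* The packaged signature and cohort tables are transcriptions; the study's
  prior-overlap count is internally inconsistent in print (36 vs 35; the
  transcription carries 37 marks), and the printed HN mean age (52.8) does
  not match the arithmetic mean of the printed HN ages (51.8). The package
  reports computed values.
* Per-reaction raw CTs for the study's own validation are unpublished, so
  its exact validation rates (87/84/76/58%) are not reproducible; the qPCR
  stage is validated against synthetic cohorts with known planted folds.
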