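# Methods

## Problem setting

Crowd workers watch short videos of children (half with an autism
diagnosis, half neurotypical controls) and answer M = 13 multiple-choice
questions about observed behaviors. The answers form categorical ordinal
feature vectors consumed by a previously trained binary logistic
regression classifier. Each worker's performance is summarized as their
mean **probability of the correct class (PCC)**: for a response with
autism probability p, PCC is p when the video's true class is autism and
1 − p otherwise. The scientific question is whether behavioral metrics
computed *without any diagnostic ground truth* — purely from how a worker
rates — predict that performance, so that trustworthy workers can be
screened before exposure to sensitive data.

## The metrics

For a worker who rated N distinct videos (first attempt), with
A_{i,j,k} the answer to question j on video i at administration k:

- **MSCL1** (mean same-child L1 distance) =
  (Σ_i Σ_j |A_{i,j,2} − A_{i,j,1}|) / N over the N videos rated at both
  administrations (pairing is strict by video id). Test–retest
  reliability; a value of 13 means the worker moved one ordinal level per
  question on average.
- **MPIL1** (mean pairwise internal L1 distance) = mean L1 distance over
  all N(N−1)/2 unordered pairs of first-attempt answer vectors. Zero is
  the copy-paste signature.
- **PT** (penalized time): a worker never warned for rating faster than
  the threshold T receives the baseline score M. Otherwise PT =
  (Σ over rated videos of t1 + t2)/N + c · RMSCL1, where t1 is the
  initial rating time, t2 the post-warning revision time (0 where no
  revision happened) and **RMSCL1** the mean L1 distance between
  original and revised answers over warned-and-revised videos. The time
  sum ranges over *all* first-attempt rated videos, the only reading
  consistent with a per-worker metric when only some ratings trigger the
  warning; the warned-videos-only alternative would change PT for mixed
  workers but not the pipeline around it.
- **Mean time** = mean t1 over first-attempt ratings, in seconds.

A worker enters the metric table only with ≥ `min_videos_metrics` (10)
distinct first-attempt videos. A metric whose own precondition fails (no
retest, fewer than two videos, no warned-and-revised video) is recorded
as an explicit absence, never as zero: the missingness structure is
itself informative (low-engagement workers skip retests and revisions)
and downstream cohort sizes must reflect it. A warned worker with no
revision record has undefined RMSCL1 and hence undefined PT.

`rescale_mean_time` carries a mean rating time across task lengths
proportionally (t · M_new / M_old), the calculation used to justify a
minimum-time threshold from a longer pilot task.

## Statistical pipeline

- **Correlation screen.** Pearson r between each metric and mean PCC,
  two-sided p from the t distribution (`scipy.stats.pearsonr`). A worker
  is eligible for a given metric only when the metric is defined and its
  underlying per-worker data-point count is at least
  `min_points_analysis` (5): retest videos for MSCL1, rated videos for
  MPIL1/PT/mean time, revised videos for RMSCL1. The Bonferroni flag is
  p < 0.05/4 over the four primary metrics. Rank correlations are
  deliberately not offered; the screen is about linear association with
  a probability.
- **c-sweep.** PT decomposes per worker as base + c · RMSCL1 (base = M,
  slope 0 for never-warned workers), so the sweep over the 200-point
  grid [0.05, 10.0] (step 0.05) costs one pass over the data.
  `any_positive` is true iff some grid point has r > 0 with p < 0.05.
  When PT is constant across workers (nobody warned) r is undefined and
  reported as NaN.
- **Subset regressions.** OLS of mean PCC on every non-empty subset of
  {MSCL1, MPIL1, mean time} with worker-level 5-fold cross-validation:
  workers are shuffled once by the seed (`numpy` Generator permutation)
  and split into 5 near-equal folds; a worker's videos are never split
  across folds because the predicted unit is the worker's mean PCC. MAE
  is the pooled mean absolute held-out error × 100 (percentage points of
  PCC). Each subset is evaluated both on its own maximal cohort (all
  workers with that subset defined — cohort size varies with
  missingness) and on the fixed intersection cohort with all three
  metrics defined. Reported coefficients come from the full-cohort fit.
  An intercept-only baseline (fold-train mean) with the identical fold
  construction is provided for calibration.
- **Cross-cohort evaluation.** Fit on one cohort (no CV), evaluate MAE
  on a second cohort with disjoint worker ids (enforced; overlap raises)
  and, by design, disjoint videos (overlapping video ids only warn when
  id sets are supplied, since the metrics table itself carries no video
  ids). The same fit's training-cohort MAE is reported alongside so the
  generalization gap is visible.

All analysis outputs are deterministic given inputs and seed.

## Synthetic study generator

No worker-level data from the original study are available, so the
simulator generates cohorts that reproduce the *mechanics* the metrics
measure. Defaults are the study conditions: 24 videos balanced 12/12,
60 workers, 13 questions, 4 ordinal levels per question (the true answer
scales are not documented; four-level scales are typical of behavioral
feature questionnaires and the count is configurable), T = 120 s, and a
full second administration of every video.

- **Classifier and videos.** Ground-truth weights are standard normal;
  the intercept calibrates the mid-scale neutral vector to probability
  0.5. Each video's latent "ideal" answer vector is drawn by pushing a
  growing fraction of questions to the class-consistent extreme of their
  scale until the classifier gives the correct class probability
  ≥ 0.8, leaving the remaining questions uniform so ideal vectors vary
  within a class.
- **Workers.** Diligence d ~ Beta(2, 2). Each worker has a habitual
  default answer vector (uniform). On each question the worker answers
  the ideal code plus rounded, clipped N(0, 0.8) noise with probability
  d, and their default otherwise. Lazy workers (15% in coupled mode)
  always answer their default. This anchoring mechanism is what couples
  the answer-domain metrics to performance: answers that collapse onto
  one vector give both MPIL1 → 0 and mean PCC → 0.5 (exactly 0.5 in
  expectation on a balanced video set), so the generator-implied sign of
  r(MPIL1, mean PCC) is positive. Retest answers re-run the process with
  noise SD sqrt(0.8² + 0.5²); low-diligence workers preferentially skip
  the retest (probability clip(0.5·(1.3 − 1.6 d), 0, 0.9)), reproducing
  the observation that poor performers are missing from the
  retest-dependent metrics.
- **Times and warnings.** t1 is log-normal around a per-worker rate; in
  coupled mode the rate rises with diligence (90 + 120 d ± 15 s, lazy
  workers uniform 40–140 s), so some workers rate under the 120 s
  threshold and are warned. A warned rating is revised with probability
  0.25 + 0.7·effort; in coupled mode effort equals diligence and the
  revision moves answers toward the ideal vector proportionally to
  effort.
- **Null mode** (`couple_quality=False`): no lazy workers; rating speed
  and revision effort are drawn independently of diligence and revisions
  are undirected unit perturbations. Performance still varies (through
  d) but carries no information into the time/revision channel — the
  regime in which the penalized-time sweep should find nothing.

What the generator does **not** emulate: question semantics or
item-level difficulty (questions are exchangeable), worker learning over
time, heaping/rounding in recorded times, platform-level selection
effects, or the real answer-scale cardinalities. Passing recovery tests
therefore shows the pipeline detects the mechanisms it targets under a
plausible behavioral model, not that real cohorts have these effect
sizes; in particular the synthetic correlations are stronger than those
reported for real workers, since the generator contains no unmodeled
heterogeneity.

## Numerical and design choices

- Answer codes are 0-based consecutive integers per question; ordinal
  codes enter the classifier's linear predictor as plain integers. A
  different encoding would be a local change to `predict_probability`.
- Classification at the threshold: p equal to the threshold goes to the
  positive class (a convention; the probability scale makes ties
  measure-zero in practice).
- Mean PCC uses first-attempt ratings only by default (revised and
  retest answers are scorable via flags), so each worker contributes one
  performance figure.
- `warned` is recorded in the data, not re-derived, but ingestion
  cross-checks it against t1 < T and warns on inconsistencies; CSV
  reads use round-trip float parsing so write-then-read is exact.
- CV MAE is the pooled mean over all held-out predictions (fold sizes
  differ by ≤ 1, so this is within rounding of averaging fold means).
- Default c = 1.0 for single-value PT reporting; no preferred c exists,
  which is exactly what the sweep operation is for.
- Problem sizes in the test suite (50–100 simulated workers, 30–50
  replicates for recovery checks) keep the full suite under a minute
  while leaving the monotonicity and sign checks far from their decision
  boundaries.

## Known limitations

- The PT baseline M is a score in "question count" units while the
  warned branch is in seconds; the two branches are not commensurable,
  which is faithful to the metric's definition and one reason PT
  correlates poorly.
- With 4-level scales the maximal L1 per pair is Σ(L_j − 1) = 39; MSCL1
  and MPIL1 near that bound require adversarial vectors the generator
  never produces.
- `fit_subset_regressions` raises rather than skips when a cohort is
  smaller than the fold count; callers with heavy missingness should
  drop the subset or lower k explicitly.
- Cross-cohort evaluation assumes the two cohorts share the metric
  scale; no recalibration (e.g. standardization per cohort) is applied.
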