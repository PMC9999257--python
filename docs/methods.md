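# Methods

## The prediction problem

Each participant contributes an ordered series of scheduled EMA prompts.
At prompt *t* the participant reports 31 antecedent states (affect,
craving, context) and whether the current eating episode was a binge;
self-initiated event reports can additionally flag overeating episodes
between prompts. The target is the binary *objective binge-eating
episode* at prompt *t+1* — an episode with both an objectively large
amount of food and a sense of loss of control — predicted about 2.5 h
ahead from the states at *t*. Modeling is strictly idiographic: every
participant gets their own predictor subset and their own accuracy
estimates; cohort statistics are means and sample SDs over participants.

## Data preparation

- **Criterion.** A prompt is a binge (1) if its meal-type answer is
  "binge" or any event report mapped to its window has
  excessive-amount = yes *and* loss-of-control = yes; 0 otherwise;
  missing if the prompt is unanswered and no qualifying event exists.
  Event reports with a missing criterion field are rejected with a
  warning. Events are mapped to the prompt whose window
  (previous prompt, this prompt] contains them, with day-bounded edges:
  the first prompt of a day also absorbs events from midnight, the last
  prompt events up to the end of its calendar day. Calendar-day
  boundaries use the local date; the default schedule (08:00–20:30)
  never crosses midnight.
- **Day padding.** One all-missing row is inserted after the last prompt
  of every day. Together with the backward shift this guarantees no
  (predictor, criterion) pair spans the overnight gap.
- **Criterion shift.** y at row *i* is the binge indicator at row
  *i+1*; missing where row *i+1* is padding or absent.
- **Time predictors.** Cumulative hours Δt accumulate the *scheduled*
  inter-prompt differences (2.5, 5, 7.5, …), not actual response times,
  so the cyclical features sin(2π/T·Δt), cos(2π/T·Δt) for T ∈ {8, 12,
  24} lie exactly on the design grid. Six time-of-day dummies map
  positionally from the six scheduled slots (morning … late evening).
- **Missingness.** Unanswered prompts keep their row (time features
  exist; the criterion may still be known from the next prompt);
  no imputation is performed. All correlations downstream are
  pairwise-complete and scale scores prorate over observed items.

## BISCUIT

For one participant with predictor matrix X (44 candidates) and shifted
criterion y (padding and missing-y rows excluded; at least two rows of
each class required):

1. **Ranking.** r_j = pairwise-complete Pearson correlation of
   predictor j with y (point-biserial, since y is binary). Undefined
   correlations (constant series, <3 complete pairs) exclude the
   predictor from ranking. Ties in |r| break by canonical predictor
   index so results are deterministic.
2. **Unit-weighted scale.** The top-k predictors by |r|, each keyed by
   sign(r_j); the score of a row is the mean over *observed* keyed items
   of key_j · z_j, with z standardized by the derivation rows' mean and
   population SD (ddof = 0 — any affine rescaling of a predictor cancels
   either way). Standardization statistics always come from training
   rows only.
3. **Choice of k.** Seeded stratified 10-fold cross-validation: each
   fold ranks predictors on its training rows, builds the top-k scale
   for every k in the grid (default 1..20), and records the correlation
   of the held-out scores with y. The retained k maximizes the mean
   held-out correlation (ties to the smallest k); the final scale is
   refit on all rows at that k. Stratification deals each class out
   round-robin after an in-class shuffle, so participants with fewer
   positives than folds still get as even a spread as possible; plain
   (unstratified) CV is available via a flag.
4. **Reliabilities.** r_D and r_CV are fold-wise derivation and
   validation correlations summarized as mean and sample SD. They come
   from a *nested* cross-validation: each outer fold re-chooses k by an
   inner CV on its training rows only, then the outer held-out
   correlation is recorded. Reporting the maximizing k's own CV folds
   would be the maximum of ~20 noisy means and is badly biased (we
   measured a null mean r_CV of ≈ +0.28, and re-partitioning the same
   data does not remove it since the chance correlations live in the
   data); the nested estimate is centered on zero under the null. Outer
   folds whose training rows are too sparse in positives to re-choose k
   (e.g. a participant with 2 binges) fall back to the globally chosen
   k so the diagnostics stay defined.

Plain X-fold CV (not rolling-origin) is the primary scheme even though
EMA rows are serially dependent; the item autocorrelation in the
generator (φ = 0.5) makes the synthetic checks honest about this
choice's optimism rather than hiding it.

## Evaluation

- **AUC** is computed with midranks, exactly equal to counting
  positive–negative pairs with half credit for ties. The bootstrap CI is
  a stratified percentile interval (resampling within class, B = 2000 by
  default), so every resample retains both classes.
- **Cutoff.** All midpoints between adjacent distinct scores plus ±∞ are
  scanned; predicted-positive means score ≥ cutoff; the cutoff
  maximizing Youden's J = sensitivity + specificity − 1 is retained,
  with ties going to the *smallest* cutoff — for a just-in-time
  intervention a missed binge costs more than a false alarm.
- Sensitivity and specificity are in-sample properties of the
  full-sample scale and cutoff, and are labeled as such; only r_CV is an
  out-of-sample quantity.
- Cohort aggregation uses the arithmetic mean and sample SD (n − 1),
  with SD reported as missing for a single participant. The "mean 95%
  CI" is the mean of lower bounds and the mean of upper bounds —
  averaging interval endpoints is unusual but is the cohort reporting
  convention this package mirrors. Participant metrics are carried at
  6-decimal working precision (so the written table re-aggregates to the
  written summary exactly) and rounded to 2 decimals only for display.
  Selection-matrix significance stars use the t approximation
  t = r√((n−2)/(1−r²)) with pairwise-complete n, two-tailed, unadjusted
  for multiple testing and labeled as such.

## Synthetic data generator

The generator emulates the study design so that every stage is testable
without any real data:

- **Schedule:** 14 days × 6 prompts at 2.5 h from 08:00 (84 prompts).
- **Items:** 27 sliders (0–100) as AR(1) processes x_t = μ + φ(x_{t−1} −
  μ) + ε, φ = 0.5, μ = 40, innovation SD 15, clipped to [0, 100]; 4
  binary context items threshold the same latent process at its mean.
  Defaults are design choices (per-item distributions of real EMA data
  are not modeled); effects act on z-standardized states so their scale
  is per-SD.
- **Outcome:** binge at prompt *t* ~ Bernoulli(expit(β₀ + cycle + slot
  + Σ_j effect_j·z_j(t−1) + ar·binge(t−1))), with the antecedent terms
  dropped at each day's first prompt (no same-day predecessor).
  β₀ = logit(0.125) targets the observed episode frequency (≈10 of 84).
- **Compliance:** prompts are unanswered MCAR at rate 0.2 (≈80%
  compliance, matching the observed mean of 67.3/84 answered); item-level
  missingness is not modeled because submission required all items.
- **Event reports:** each binge independently triggers an
  event-contingent report with probability 0.6, timestamped uniformly in
  the preceding inter-prompt window; non-qualifying reports (excessive
  amount without loss of control) occur at rate 0.05/prompt so the
  criterion's rejection branch is exercised. A binge at an unanswered
  prompt is therefore only observable through an event report — some
  true episodes are missing from the derived criterion, as in real data.
- **Cohort defaults:** 13 participants, each with 3 idiographic driver
  items drawn uniformly from the sliders, effect magnitudes U(0.8, 1.2)
  with random sign.

What the generator does **not** emulate: inter-item correlation
structure (items are independent AR(1) processes), diurnal item rhythms,
reactive or burst missingness, non-stationarity across the two weeks,
and compensatory behaviors. Passing recovery/calibration tests therefore
show the algorithmic pipeline is correct and calibrated under a
plausible data-generating process, not that real EMA data meet these
assumptions.

## Numerical and degenerate-input conventions

- All randomness flows through `numpy.random.default_rng` seeds; fixed
  seeds give bit-identical outputs (fold assignment, bootstrap,
  generation).
- Correlations are undefined (NaN with a warning) for constant series or
  <3 complete pairs; undefined folds are excluded from summaries; all
  folds undefined is an error.
- A predictor constant in a training fold gets an undefined SD and
  contributes nothing to that fold's scores.
- Scale scores with every keyed item missing are NaN and the row drops
  out of evaluation.
- `optimal_cutoff` on all-tied scores returns the −∞ cutoff (sensitivity
  1, specificity 0) by the smallest-cutoff tie rule.

## Known limitations

- With ~50 usable rows and ~6 observed positives per participant,
  single-item correlations have SE ≈ 0.15: selection is noisy and the
  chosen subset mixes true drivers with chance correlates (visible in
  the README example). This is a property of the design's power, not of
  the implementation, and it is why r_CV is small and highly variable.
- In-sample AUC/sensitivity/specificity of a selected scale are
  optimistic; the honest out-of-sample quantity reported is r_CV.
- Only one-step-ahead (t+1) prediction is supported; no interaction
  terms or nonlinear expansions are considered.
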