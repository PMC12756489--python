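# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## Lexicon matching

A lexicon is an ordered list of categories, each an ordered list of phrases.
Order matters twice: category order fixes the feature-column order of every
design matrix (so stratified and temporal fits join exactly), and phrase
order breaks ties deterministically during matching.

Compilation turns each phrase into a regular expression over
NFKC-normalized, case-folded text.  Tokens are maximal runs of letters or
digits; the underscore and all punctuation count as separators.  A compiled
phrase requires its tokens in order, separated by one or more
separator characters, and anchored so that no letter/digit directly abuts
the match on either side.  There is deliberately no stemming, lemmatization
or edit-distance matching: counts must be auditable against exact text
spans, and the word-boundary definition (letter/digit transitions after
normalization) is language-neutral, so the matcher behaves identically for
Hebrew and Latin scripts (case folding is a no-op for caseless scripts).

Counting is per category: all candidate occurrences of all of the category's
phrases are enumerated, then selected greedily left to right, preferring the
leftmost start and, at equal start, the longest match; selected spans never
overlap within a category.  Categories are independent constructs, so the
same text span may count toward several categories.  The counting unit is
the occurrence (not binary presence), because the reported odds ratios are
per-mention effects; a binary-presence switch exists in the feature options.
Two consequences worth knowing: a phrase wholly contained in a longer
selected phrase of the same category is absorbed (not double-counted), and
because message texts are concatenated with a sentence break before
matching, a multi-token phrase split across two consecutive help-seeker
messages still matches — the separator-tolerance rule treats the join as
punctuation.

## Sessions, cleaning, and prefix slicing

Cleaning applies NFKC normalization, removes URLs, markup tags and control
characters, collapses whitespace, trims, and case-folds.  It is idempotent.

The five progress stages (20–100%) slice a session to the shortest
whole-message prefix whose cumulative *help-seeker* character count (after
cleaning) reaches the target fraction of the session's help-seeker total.
Character count over help-seeker text was chosen as the slicing unit because
risk language lives in help-seeker turns and character mass is robust to
message-length variance; a message-count alternative is exposed via
`FeatureOptions(slice_unit="messages")`.  Prefixes are nested in the
fraction, and the 100% slice is the identity.  Only help-seeker text is
matched — counselor turns would leak intervention language into the
features — but counselor messages inside the prefix are preserved for
context.

## Logistic model and inference

Every model is a multivariable logistic regression of the binary SR label on
all lexicon-category counts plus an intercept.  Fitting is Newton–Raphson
with step halving (monotone likelihood), converging when the largest score
component falls below 1e-8 or the relative log-likelihood change falls below
1e-10, with at most 100 iterations.  Quasi-complete separation is detected
two ways: a coefficient diverging past ±30 mid-iteration, or a "converged"
solution (vanished score) with a coefficient beyond ±15 — under separation
the score vanishes precisely because fitted probabilities saturate, so both
symptoms mark the same pathology.  Separated fits are returned flagged with
the covariance withheld; requesting effects from them is an error rather
than a table of meaningless intervals.

Confidence intervals are Wald on the log-odds scale (covariance = inverse
observed information), exponentiated to the OR scale; profile-likelihood
intervals are not implemented.  Significance is p < 0.05 per predictor with
no multiplicity correction by default, matching standard subgroup-analysis
reporting; a Benjamini–Hochberg option exists but is off by default because
the effects table is interpreted as a set of pre-specified theory-driven
hypotheses, not a discovery scan.  No regularization is applied: penalties
would bias the ORs and invalidate the Wald intervals.

The Hosmer–Lemeshow statistic sorts rows by fitted probability into 10
near-equal bins, keeping tied predictions in one bin, and sums
(obs − exp)²/exp over both outcome classes; df = bins − 2.  An empty or
zero-expectation bin raises an error advising fewer bins (this happens,
e.g., for intercept-only models where all predictions tie).

Stratified fits run one model per stratum: All/Women/Men for gender, the
four developmental bins for age.  Sessions with unknown gender or age stay
in "All" and drop out of the corresponding stratified models, mirroring
standard sample-accounting discipline.  Temporal trajectories refit the full
model on each prefix fraction (repeated cross-sections; no longitudinal
model), so the 100% point coincides exactly with the static fit.  No formal
cross-stratum coefficient tests are part of the reporting surface; a Wald
contrast utility is provided separately and labelled an extension.  The
corpus is matched once per fraction and the count matrix shared across
strata, which makes the 3-strata × 5-fraction sweep cost five matcher
passes, not fifteen.

## Evaluation

ROC-AUC is computed rank-based (Mann–Whitney with midranks), which equals
trapezoidal integration of the empirical ROC; a dual-implementation test
verifies the identity under heavy ties.  Precision, recall and F_β follow
the usual definitions with zero-denominator conventions (metric = 0 plus a
warning); F₂ weights recall twice as heavily as precision.  The
classification threshold defaults to 0.5 and is configurable — no threshold
tuning is performed.  Cohen's κ handles two raters; a panel of three or more
is reduced to the mean of pairwise κs by default (Fleiss' κ is available),
and κ is undefined (error) when expected agreement is 1.

## The synthetic generator

Real crisis chats are confidential, so the generator is a first-class,
tested component, not a fixture.  It emulates the study conditions of a
17,564-session helpline corpus:

* **Groups.** Gender (female/male/unknown) and age group (four bins +
  unknown) are drawn independently with probabilities proportional to the
  published sample margins.
* **Counts.** For category *j*, stage *s* ∈ 1..5, counts are
  X<sub>js</sub> ~ Poisson(λ<sub>js</sub> · mult<sub>j,gender</sub>),
  independent across categories (a correlation structure is a known
  limitation, see below).
* **Label.** SR ~ Bernoulli(logistic(b₀<sub>cell</sub> + Σ<sub>js</sub>
  β<sub>j</sub> w<sub>js</sub> X<sub>js</sub>)).  The default stage weights
  w are all ones, so the label depends only on per-category totals — exactly
  the conditional model the pipeline fits, which makes parameter recovery
  well-posed.  Rising weights (optional, per category) let late mentions
  carry more signal than early ones; this is the generative mechanism behind
  rising odds-ratio trajectories, reflecting that escalation of risk
  language within a chat is the phenomenon the temporal analysis measures.
* **Intercepts.** b₀ is calibrated per (gender × age) cell to hit the cell's
  target prevalence by 1-D root finding on E[logistic(b₀ + S)], where the
  distribution of S = Σ β w X is computed exactly by grid convolution of the
  Poisson terms (step 2e-4; Poisson tails truncated at mass 1e-12), not by
  Monte Carlo.  With all effects zero the closed form logit(target) is used.
  Published prevalences are marginal by gender and by age; joint cell
  targets are constructed logit-additively, logit(p_ga) = logit(p_g) +
  logit(p_a) − logit(p_all), which reproduces both margins to well within
  binomial noise.
* **Text.** Each stage renders as a fixed number of help-seeker messages
  interleaved with counselor filler.  Planted phrases are drawn from the
  category's phrase list, separated by at least one filler token, and never
  span messages; the filler vocabulary is token-disjoint from every lexicon
  phrase (validated at build time, as is the absence of cross-category
  phrase containment), so the matcher recovers the planted counts *exactly*.
  All five stages of a session are padded with length-graded filler tokens
  to identical cleaned help-seeker character lengths, so the character
  fraction s/5 slices exactly stages 1..s — temporal analyses align with
  generator stages by construction.

### Default study conditions

`default_config()` fixes n = 17,564; group probabilities and per-cell target
prevalences from the published margins (≈15.0–21.4% across subgroups); and
per-mention true odds ratios at the published gender-specific point
estimates — previous attempt 1.29/1.26 (women/men), hopelessness 1.24/1.29,
self-harm 1.17/1.16, loneliness 1.07 in women only, thwarted belongingness
1.06/1.12, depression 1.03 in men only, bullying 0.91 (protective) in women
— all other categories null.  Per-chat expected mention counts are not
published anywhere, so they are package choices fixed at values a crisis
corpus plausibly shows and that give the stratified models adequate power at
the study's own n (e.g., 2.5 expected self-harm mentions, 1.5 loneliness,
0.8 hopelessness, 4.0 depression, 0.5 for null categories).  Depression and
thwarted belongingness get late-weighted stage intensities (stage shape
0.10/0.14/0.18/0.26/0.32 × 5).

Two purpose-built corpora support the temporal tests: an *escalating*
construct (late-weighted intensity, outcome stage weights rising 0.5→1.5,
per-mention OR 1.6) whose prefix-refit OR path rises monotonically in
expectation, and a *steady* construct (uniform intensity, uniform weights,
OR 1.2 at 1.5 mentions/chat) whose path is flat.  The steady effect is kept
modest deliberately: refitting on a prefix marginalizes over the unseen
remainder of the linear predictor, which attenuates early estimates by
≈ 1/√(1 + 0.35·σ²_residual); at OR 1.2 this drift is an order of magnitude
below sampling noise, so the null really is flat, while at large
effect-times-rate products it would masquerade as a weak rising trend.

### Replicate studies and what runs where

Parameter-recovery, trajectory, and stratification studies
(`recovery_study`, `trajectory_study`, `stratification_study`) operate on
the generator's count layer directly, skipping text rendering and
re-matching on every replicate.  This is exact, not approximate: the
rendered-text route reproduces the count layer with zero mismatches (the
keystone end-to-end test asserts this over 10,000 rendered sessions and per
stage), so both routes estimate identical models.  It also keeps 100-replicate
studies at n = 17,564 in the tens of seconds.

## What passing tests do and do not show

The generator plants independent Poisson counts and a correctly specified
logistic label.  Passing recovery and coverage tests therefore demonstrates
the *inferential machinery* — matching, design assembly, ML fitting, Wald
intervals — not that real chats satisfy the model.  Real corpora have
correlated constructs, length-heterogeneous sessions, and linguistic
variation the toy lexicon cannot represent.  Two concrete gaps:

* **Discrimination.** With the published per-mention effect sizes
  (ORs 0.91–1.29) and mention counts consistent with the published CI
  widths, the synthetic linear predictor has variance ≈ 0.18, which caps
  held-out ROC-AUC near 0.62.  The much higher discrimination reported on
  real data must come from signal the independence-default generator does
  not model (correlated constructs, richer lexical coverage, heterogeneous
  base rates), so held-out AUC on synthetic corpora is a sanity check
  (> 0.5), not a reproduction target.
* **Prevalence margins.** At the smallest subgroup (n ≈ 1,467) one
  percentage point is about one binomial standard deviation, so realized
  margins fluctuate by ±2 pp across seeds; fixed-seed tests make the check
  deterministic.

## Numerical choices and degenerate inputs

* Logistic convergence: score tolerance 1e-8, relative LL tolerance 1e-10,
  100 iterations, 30 step-halvings; separation bounds ±30 (divergence) and
  ±15 (saturated convergence).
* Matching tie-break: leftmost start, then longest span, then lowest phrase
  index — fully deterministic.
* Calibration root-finding: Brent's method on [−35, 15], xtol 1e-10; an
  unattainable target raises.
* Empty text → zero counts; empty lexicon files, duplicate category ids,
  zero-phrase categories, phrases that normalize to nothing → hard errors.
* A stratum that is empty or single-class raises an error naming the
  stratum (and the fraction, in temporal runs); constant non-intercept
  columns are rejected before fitting.
* Seeds: every stochastic component takes a `numpy` Generator or integer
  seed; identical config + seed reproduces corpora byte-for-byte.

## Known limitations

Constructs are generated independently (an optional correlation structure is
future work); the toy lexicon is an English stand-in instrument, not a
validated clinical lexicon; no negation handling (deliberate — the matching
rules are part of the method); cross-sectional sessions only, no
longitudinal linkage; thresholded metrics use a fixed 0.5 cutoff unless
configured otherwise.
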