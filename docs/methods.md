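# Methods

## Scope and model of the screening process

`safescreen` simulates prioritized title/abstract screening as a sequential
decision process over a labeled corpus. A *screener* is an oracle that
answers from the corpus labels; the *perfect* screener never errs, the
*noisy* screener flips a truly relevant record to irrelevant with a fixed
false-negative probability (default 0.10, the ballpark of reported human
miss rates) and never errs in the other direction. The flip decision is a
deterministic function of (seed, record id), so it does not depend on the
order in which records are presented. The quality-check phase (phase 4) is
screened by an error-free second screener: its purpose is to catch first
screener errors, and simulating it with the same noisy oracle would make the
phase vacuous.

Assumptions inherited from the screening workflow being modeled:

- oracle labels exist for every record (simulation mode; the framework is
  an evaluation harness, not an interactive screening tool);
- key papers are known a priori, present in the dataset, and truly
  relevant — a designated key paper missing from the corpus blocks the
  active-learning phase unless explicitly waived, because the
  all-key-papers-found condition could then never hold;
- input quality matters ("garbage in, garbage out"): validation reports
  duplicates (exact match on lowercased, whitespace-collapsed
  title+abstract; deduplication keeps the first occurrence), records with
  no text, and missing years. Records with only a title are retained and
  ranked on the title alone.

## Phases and stopping rules

**Phase 1 (training).** Sample size n₁ = min(T, max(phase1_min,
⌈phase1_fraction·T⌉)); defaults 50 and 1%. The 1% rule alone is known to
be unreliable on small datasets (1% of 500 records is a 5-record sample),
hence the floor. Stratified selection takes the k oldest and k newest
records by year with k = ⌈n₁/10⌉ plus seeded random intermediates;
records without a year are eligible only for the random stratum. The
stated stopping rule ("a minimum of records or until a relevant record is
found") is ambiguous between an OR and an AND reading; the engine
implements the conservative AND: it screens n₁ records *and* continues
with random draws until both classes are present, since the first model
cannot be fit otherwise. The prevalence estimate is always computed from
the full final phase-1 set, including any overshoot.

**Phase 2 (active learning).** Certainty-based selection: refit on all
labels (cadence `refit_interval`, default every label), present the
top-ranked unscreened record. The composite stopping rule is evaluated
after every label and stopping takes effect at the first satisfying
record; batch evaluation could overshoot nondeterministically. The two
count floors (2 × RR_T and 10% of T) are cumulative over phases 1+2:
training labels are screening effort too. If the pool empties first, the
phase reports a census with the unmet conditions in its diagnostics rather
than erroring — on small corpora screening everything is a legitimate
outcome.

**Phases 3 and 4 (model switch, quality check).** The
consecutive-irrelevant window (default 50) is scoped to the phase: each
phase re-ranks with a different model, and a streak accumulated under the
previous model says nothing about the new ordering. A relevant find resets
the streak; this criterion is deliberately non-monotone. Phase 4 trains on
pseudo-labels — the 10 highest-ranked records of the final phase-3 ranking
as relevant, the 10 lowest as irrelevant. With fewer than 20 ranked
records the split degrades to halves (with a warning); if phase 3 ran to a
census there is no final ranking at all, and the phase-4 model falls back
to the accumulated real labels. Phase-4 decisions are logged as
corrections: a relevant find overrides the record's earlier exclusion, and
counts are conserved (records move between included/excluded, totals never
change).

## Ranking models

*simple_lexical*: TF-IDF over lowercased alphanumeric word unigrams
(min document frequency 1, smoothed IDF, L2-normalized rows) with
multinomial naive Bayes (default) or liblinear logistic regression.
Scores are monotone relevance scores, not calibrated probabilities; only
the induced order matters.

*alternative* (`char_svd`): TF-IDF over 3–4 character n-grams →
100-component truncated SVD → a 16-unit single-hidden-layer MLP with
strong L2 weight decay (alpha = 10). The char n-grams give partial credit
for shared stems and morphology that word unigrams treat as disjoint
vocabulary — the inductive bias the model-switching phase needs. The heavy
regularization is load-bearing: the embeddings are low-dimensional and the
training sets tiny (tens to a few hundred labels), and a lightly
regularized MLP latches onto a few high-variance directions and loses the
stem signal entirely. This family is a deliberately deterministic,
dependency-free stand-in with a *different inductive bias*, not a
pretrained sentence embedder; a registry (`register_model_family`) lets
users plug in a true neural/sentence-embedding model.

Rankings are strict total orders: descending score with ties broken by
ascending record id, so permuting the input can never change the output.
The unsupervised feature extractors may be fit once on the full corpus
(`prepare`), which labels never enter; this makes per-label refits cheap.

## Prevalence estimation

FRR_t = RR_t/t requires RR_t ≥ 1 (guaranteed by the phase-1 stopping
rule). RR_T = ⌈FRR_t·T⌉ uses a ceiling, never rounding: the estimate
feeds a minimum-screening floor and a conservative procedure must not
shrink it. Under pure random sampling the estimator is unbiased up to the
ceiling and the exclusion of zero-relevant samples; under the stratified
oldest/newest selection no unbiasedness is claimed. An optional exact
hypergeometric upper confidence bound (`upper_bound_relevant`, largest R
such that observing ≤ RR_t relevant in the sample retains probability
≥ 1 − confidence) is provided for users wanting a conservative alternative;
it is off by default and nothing in the default procedure consumes it.

## Numerical choices

- Every fraction-of-count threshold (⌈min_fraction·T⌉, ⌈FRR_t·T⌉,
  phase-1 sizing, the 95%-recall target) takes the ceiling of the *exact
  rational* value of the fraction via `Fraction(...).limit_denominator`:
  in binary floating point 0.1 × 200 is 20.000000000000004 and 0.05 ×
  10000 is 500.00000000000006, whose naive ceilings silently inflate the
  thresholds by one.
- One master seed expands into independent per-component seeds (phase-1
  sampling, screener noise, each model, the Monte-Carlo baseline) through
  `numpy.random.SeedSequence.spawn`; identical (corpus, config, seed)
  reproduces the screening log and metrics byte-identically.
- Degenerate inputs: empty corpora, all-irrelevant corpora (the procedure
  is undefined with R = 0) and single-class corpora raise; window = 1 and
  tiny corpora run to censuses rather than crash.

## The synthetic corpus generator

The generator emulates the *ranking geometry* a screening corpus presents
to a lexical relevance model — not natural language. Documents are token
streams over a pseudo-word vocabulary: a Zipf-weighted background
distribution shared by all records, plus a class topic mixed in with
weight separability/(1 + separability). Defaults (1,000 records, 5%
prevalence, separability 3 → 75% topic tokens in relevant records, mean
document length 60 tokens, 3 key papers) describe a small, well-separated
review corpus, the regime in which prioritized screening is worth using.
The relevant count is exact (round(prevalence · n), not binomial) so
evaluation has a known true R.

Two structural features exist specifically to exercise the later phases:

- **Hard relevants** (`hard_fraction` of the relevant records) draw their
  topic tokens from a divergent vocabulary: each hard term keeps the
  6-character stem of a main-topic term but a different suffix, so the two
  topics share no word unigrams but overlap in character n-grams. The
  divergent terms are *ambiguous*: they also occur diffusely
  (`ambient_hard_rate`, default 0.10) in irrelevant records. Both halves
  are needed. The ambient occurrences make word-level models learn the
  divergent terms as evidence of irrelevance, burying hard records (without
  them, discriminative rankers place unusual documents just below the
  relevants — the "odd document" effect — and the active-learning phase
  finds them anyway); the shared stems let the character-level model
  connect hard records to the labeled relevants. Key papers are drawn only
  from the main topic: expert-nominated key papers sit in the core of a
  field's vocabulary, and keeping them out of the hard population
  guarantees the model-switching phase has something only it can find.
- **Noise injection** blanks abstracts and appends exact duplicates at
  seeded exact rates, to exercise input validation.

What the generator does *not* emulate — and therefore what passing tests do
not show: natural-language synonymy and paraphrase, topic drift over time,
correlated metadata quality, citation structure, multiple overlapping
relevant subtopics, and realistic class imbalance at very large T. Results
on synthetic corpora demonstrate that the procedure's machinery behaves as
specified, not that any particular recall will be achieved on a real
review corpus.

## Problem sizes in the test suite

The end-to-end suite uses T = 1,000 corpora at 5% prevalence (50
replicates for the random-baseline comparison, 20 seeds each for the
model-switching and quality-check mechanisms), T = 5,000 with 2,000
Monte-Carlo draws for the estimator, and 10,000 randomized logs with
T ≤ 200 for the brute-force stopping-rule comparison — sizes chosen so the
whole suite runs in minutes on a laptop while keeping the Monte-Carlo
standard errors well below the margins being asserted.

## Known limitations

- The screener error model is a constant per-record false-negative rate;
  real screener errors correlate with document difficulty and order.
- The pseudo-label construction in phase 4 inherits whatever the phase-3
  ranking got wrong; with a weak phase-3 model the quality-check ordering
  degrades toward random, which lowers its recovery rate but never its
  soundness (it can only "recover" records that are truly relevant).
- WSS is reported at the achieved recall (and additionally at 95% recall
  when reached); no recall *estimation* from partial screening is
  attempted, and the statistical stopping rules from that literature are
  intentionally out of scope.
- The stratified phase-1 proportions (k oldest, k newest, k = ⌈n₁/10⌉)
  are a fixed convention; the workflow being modeled names the strata but
  no proportions.
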