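# Methods

This note records the modelling assumptions, defaults, and numerical choices
behind `langdx`, in the spirit of a model-description appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The analysis

Given per-participant post corpora, demographics (age, sex, race), and a
binary condition panel, the pipeline is: cohort filters → language encoding
→ per-condition model comparison → per-topic marker scan.

### Cohort filters

Participants need at least `min_words = 500` tokens across all posts. The
threshold is inclusive (≥ 500); it is a parameter. An optional minimum post
count (`min_posts`, off by default) is also available. Conditions need at
least `min_cases = 30` cases (and as many controls) to be evaluated; a
condition may be restricted to one sex (e.g. pregnancy to females), in
which case all of its analyses run on that subset only.

### Language encoding

- **Tokenizer**: lowercases; collapses URLs to `<url>` and @-handles to
  `<user>`; keeps emoticons as single tokens; a run of one repeated
  punctuation character is one token. No lemmatization, stop-word removal,
  or spelling correction — misspellings and slang are signal, not noise.
- **Grams**: unigram and bigram counts (bigrams never span post
  boundaries), pooled into one frequency ranking; the top `max_vocab =
  20,000` kept, ties broken lexicographically. Relative frequencies are
  normalized per order (unigram counts over the participant's unigram
  total, bigram counts over the bigram total) — a choice, since only the
  gram set, not the normalization, is canonical.
- **Topics**: LDA over participant-level unigram counts (one document per
  participant), `n_topics = 200` by default. The engine is scikit-learn's
  batch variational implementation; document concentration defaults to
  `min(1, 50/K)` (the classical 50/K clipped to scikit-learn's admissible
  range), word concentration 0.01, up to `max_iter` passes with a
  perplexity convergence check every `evaluate_every = 5` passes. A
  single-topic model is handled in closed form (phi = the pooled corpus
  distribution). The topic prior p(t) is the length-weighted average of
  document topic distributions; `p(t|w) ∝ phi[t,w] p(t)` by Bayes' rule.
- **Topic scores**: `score(t,u) = Σ_w p(t|w) p(w|u)` over the
  participant's in-vocabulary unigrams. Rows sum to the in-vocabulary
  mass (exactly 1 with full coverage); a participant with no in-vocabulary
  words gets a zero row and a warning. The score is exactly a word-level
  topic posterior multiplied by the participant's probability of mentioning
  the word, summed over words — an expectation of topic usage under the
  participant's word distribution.

### Feature selection

Per condition and per training fold, each candidate gram's two-sided
point-biserial (Pearson) correlation p-value against the label is
Bonferroni-adjusted (× number of grams, capped at 1) and the top
`k_grams = 500` by adjusted p (ties: raw p, then gram) are kept. Several
family-wise-error statistics are admissible for this step; the
point-biserial/Bonferroni combination is the package's default and the
statistic is isolated behind `fwer_select`. Selection sees training rows only; the evaluation layer
passes fold-masked matrices.

### Models and evaluation

- Language model: `ExtraTreesClassifier`, 1,000 estimators, Gini
  criterion, √d candidate features per split with one random threshold
  each, no depth limit, no bootstrap.
- Demographics model: ridge logistic regression on standardized predictors
  (age in decades, female indicator, race one-hot with the most common
  category as reference). Penalty strength 1.0 by default, configurable.
- Ensemble: AUC-weighted average of predicted probabilities, weights being
  each model's in-sample training-fold AUC.
- Cross-validation: stratified 10-fold, implemented by dealing shuffled
  cases then controls round-robin (fold sizes differ by ≤ 1, per-fold case
  counts by ≤ 1, guaranteed). If a class has fewer than k members, k is
  reduced with a warning.
- AUC: midrank (all-pairs concordance, ties ½).
- Model-vs-model significance: paired sign-flip Monte-Carlo permutation
  test — each iteration swaps a participant's two scores with probability
  ½ — two-sided, add-one smoothed, default 100,000 iterations. The
  sign-flip pairing is the standard choice for comparing two models scored
  on the same participants and is exposed as a named strategy.
- Model-vs-chance: label-permutation test, one-sided (greater), add-one
  smoothed.
- FDR: Benjamini–Hochberg step-up across conditions, one family per
  comparison type (language vs demographics; combined vs demographics;
  language vs chance).

### Markers

Per condition and topic: AUC of the raw topic score (rank-equivalent to
any monotone univariate model, so no fit is needed); cross-validated ridge
AUC for demographics and demographics+topic on shared folds; sign-flip
permutation p for the demographics+topic vs demographics difference; BH
across the topics within the condition. Direction is the sign of (mean
score in cases − mean score in controls). Constant topics are flagged
degenerate (AUC 0.5, p 1).

**Quartile risk ratio.** Participants are split into quartiles of the topic
score by stable sort (ties keep input order; with zero-inflated scores the
assignment is deterministic). The ratio of maximum-likelihood case
proportions (top/bottom) gets a percentile bootstrap 95% CI with 10,000
resamples drawn *within* each fixed quartile — resampling 0/1 labels within
a quartile is realized as a binomial draw of the case count, which is
distributionally identical and fast. Resamples with a zero-case bottom
quartile contribute +inf, so a one-case bottom quartile typically reports
"[finite, inf]". If the *observed* bottom quartile has no cases the ratio
is +inf and pure resampling degenerates (every resample infinite); the
bottom rate is then continuity-corrected to 1/(n+1) for the CI only,
preserving a finite lower bound. Conditioning on fixed quartile membership
(rather than re-quartiling every resample) is deliberate: it is what
produces the infinite upper bounds seen in practice for rare conditions.

**Expression matrix.** Entry = direction × (topic-alone AUC − 0.5) ∈
[−0.5, 0.5]; signed excess AUC is the package's definition of a marker's
"predictive strength". Rows are ordered by
average-linkage hierarchical clustering on Euclidean distances; conditions
are sorted by name first so the dendrogram is invariant to input order.

## The synthetic-study generator

The generator is artifact-level plumbing: no generative assumptions about
real social-media language are inherited from any study, so all choices
are made here and labelled.

- Each participant's words are drawn from a Dirichlet-multinomial topic
  mixture: topic–word rows ~ Dir(`topic_concentration = 0.05`) — sparse,
  well-separated word distributions; participant mixtures
  ~ Dir(`mixture_concentration = 0.05`) — a participant concentrates on a
  few of the 20 default themes, the sparse regime typical of per-user topic
  loadings, and the regime in which a logistic coefficient of +3 on one
  topic is a detectable effect (oracle AUC of the true topic share ≈ 0.59).
- Defaults: 1,000 participants × 600 words in 30 posts over a 500-word
  vocabulary; tokens are synthetic strings `w0001…` so tokenization is
  exact (an optional realistic-text mode appends punctuation to ~5% of
  tokens to exercise the tokenizer). Words are partitioned into posts
  uniformly at random; post boundaries only matter for bigrams.
- Demographics: age uniform on 18–65, 76% female, race mix 71/23/2/4%
  black/white/asian/other (a convenience-sample profile); encoded as age
  in decades, female indicator, race one-hot less the most common
  category.
- Conditions: `P(y=1) = logistic(intercept + β_topics·θ + β_demo·x)`;
  labels are drawn by comparing one uniform per participant-condition to
  the probability, so prevalence is monotone in the intercept at a fixed
  seed. The default panel is one condition with intercept −1.5
  (prevalence ≈ 0.21) and +3 on topic 0 — the planted-marker scenario.
- Everything is deterministic given (config, seed).

What the generator does **not** emulate: real vocabulary/Zipf structure,
emoji, temporal posting dynamics, topic correlations, label noise in EMR
coding, or demographic–language confounding. Passing recovery tests
therefore show the machinery is correct and calibrated, not that real
conditions are predictable at any particular AUC.

## Problem sizes in the test suite and acceptance script

Simulation-based checks run at deliberately scaled-down sizes chosen as
the package's own test design: planted-marker recovery and null control
use 1,000 participants × 600 words, a 250-word vocabulary, 20 true and 20
fitted topics, 2,000 candidate grams, 200 trees, 2,000 permutation
iterations, and 20 replicates; the reproducibility check uses the bundled
200-participant fixture. LDA runs up to 40 passes with the convergence
check (15 in the null control, where topic quality is immaterial) — fixed
short schedules (8 passes) were observed to leave planted topics
unconverged in a minority of runs. The full-scale defaults
(200 topics, 20,000 grams, 1,000 trees, 100,000 iterations) remain the
package defaults for real analyses.

## Known limitations

- The FWER statistic, permutation pairing, ridge penalty, clustering
  linkage, and expression transform each admit several reasonable
  definitions; each is a documented default behind a stable interface.
- ERT probabilities over an encoding with a single informative direction
  (the planted scenario's worst case) carry fold-level noise of roughly
  ±0.02–0.03 AUC at n = 1,000; comparisons near that scale are
  power-limited, which the recovery tests' replicate counts reflect.
- The permutation tests are valid but conservative by the add-one
  smoothing; with n_iter iterations no p-value is below 1/(n_iter+1).
- `topic_given_word` uses the corpus-level topic prior, not per-document
  posteriors; this matches the scoring definition but is not a full
  posterior decomposition per participant.
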