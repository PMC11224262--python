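# Methods

## The coherence statistic

Speech coherence is operationalised as the mean semantic similarity of
adjacent sentence pairs within one post.  With unit-norm sentence embeddings
e₁…eₙ, the score is Σ⟨eᵢ,eᵢ₊₁⟩/(n−1).  Only first-order (consecutive) pairs
enter; gap-k generalisations are deliberately out of scope.  Pairs are
unweighted, so long posts are not down-weighted within the statistic itself —
post length enters the analysis as a covariate instead.  The statistic is
defined only for posts with at least two sentences; the filtration stage
guarantees this precondition, and the scorer treats a violation as a
contract error rather than returning a degenerate value.

All encoders are L2-normalised (including any pretrained adapter output), so
the inner product is a cosine and the score is bounded in [−1, 1].  This
normalisation is imposed deliberately: the bounded-similarity reading of the
inner product presumes unit norms, and re-normalising costs nothing for
encoders that already emit unit vectors.

## Filtration contract

Posts are excluded, in this fixed order, when they (1) are removed/deleted
placeholders or empty after trimming, (2) contain a URL, (3) segment into
fewer than two sentences.  Each post is counted at the first rule it fails,
so the report's categories always partition the input exactly — a property
the tests fuzz.  Only the body text is evaluated; titles never substitute
for bodies.  Records shaped like comments are ignored before filtration.
URL detection is scheme-based (http/https/ftp, `www.`) plus bare domains
with a recognised TLD; this mirrors the behaviour of common URL-extraction
libraries without depending on one.

## Sentence segmentation

Segmentation is rule-based and fully inspectable: terminal punctuation
(./!/?/ellipsis) followed by whitespace and a capital (or digit), or end of
text, ends a sentence, except after entries of a shipped, user-extendable
abbreviation whitelist and single-capital initials.  Periods between digits
(decimal numbers) never split.  Hard newlines end a sentence whenever the
fragment carries at least one word token, since forum posts routinely omit
terminal punctuation at line ends.  Quoted or parenthetical sentences follow
the default rules; the segmenter is not tuned to replicate any specific
third-party tokenizer, it implements a documented contract instead.

## Sentiment covariates

Valence (∈ [−1,1]) and subjectivity (∈ [0,1]) are lexicon-based: the mean
polarity/subjectivity of matched words, with an immediately preceding
intensifier multiplying a match's polarity and a negation cue within the
preceding 3 tokens flipping-and-damping it by −0.5 (both window and factor
configurable; the convention of lexicon scorers).  The shipped lexicon is a
~400-entry curated English word list with hand-assigned polarity and
subjectivity bands plus negator and intensifier lists; it reproduces the
*mechanism* of lexicon sentiment scoring, not any specific library's scores,
and all three files are user-replaceable.  Posts with no matched word score
(0, 0).

`sentence_length` is the per-post ratio word_count / sentence_count by
default.  Because published per-forum means of "sentence length" need not
equal mean-words / mean-sentences, the alternative definition (mean of
per-sentence word counts) is available via `sentence_length_mode=
"mean_per_sentence"`.

## The built-in encoder

The hashing encoder maps a sentence to the signed-hash sum of its lowercased
word unigrams and boundary-padded character trigrams, L2-normalised
(dimension 512 by default, configurable; hash seed fixed at a documented
default so vectors are bitwise reproducible across platforms).  Sentences
sharing more surface features have higher expected inner product; sentences
with disjoint vocabulary are nearly orthogonal at d = 512 (mean |cosine|
≈ 0.07 in the Monte-Carlo test).  A sentence with no extractable features
maps to the fixed basis vector e₁ rather than the zero vector, preserving
the unit-norm contract.  This encoder measures *lexical-surface* semantic
continuity; it is blind to synonymy and word order, which is sufficient for
the synthetic studies (whose semantics are carried by vocabulary overlap)
but is not a substitute for a trained sentence encoder on real text.
Pretrained encoders register through the same unit-norm/fixed-dim contract
and are contract-checked at registration; none are downloaded or exercised
by the test suite.

## Inferential layer

The group comparison is an OLS fit of coherence on a dummy-coded group
factor (configurable reference level) plus the five text covariates, solved
by QR decomposition with an explicit rank check that names collinear
columns.  Reported per coefficient: SE, t, two-sided p, and partial
η² = t²/(t² + df_resid); per model: σ̂², R², adjusted R².

Estimated marginal means are model predictions per group with covariates at
their grand means over the estimation sample (for a two-group subsample
model, the subsample's means); SEs come from the coefficient covariance via
the prediction-vector quadratic form x'Σx.  Pairwise contrasts use the exact
per-pair SE from the same covariance (correct under unbalanced designs),
with Tukey adjustment p = P(Q_{k,ν} ≥ |t|√2).  The studentized-range tail
probability is evaluated by Gauss–Legendre quadrature of the closed-form
density (160 nodes over the normal-range integral, 80 over the scaled-chi
scale integral truncated at the 10⁻¹² quantiles); it agrees with independent
implementations to ~10⁻¹² over the tested range, and with a Monte-Carlo
range simulation in the tests.  For k = 2 the adjustment reduces to the
plain two-sided t-test p-value; this identity is special-cased so it holds
to machine precision.  Cohen's d for a contrast standardises the EMM
difference by the model residual SD (the convention of EMM post-hoc
tooling), with a large-sample normal CI (d ± 1.96·SE_diff/σ̂).

Two-sample covariate comparisons default to the Welch test with
Satterthwaite df — group sizes in this setting are typically wildly
unequal — with the pooled-variance variant available (`equal_var=True`).
Cohen's d there uses the pooled SD with the standard large-sample variance
approximation for its CI.  Post-hoc power for a two-group comparison is
computed from the noncentral t distribution with noncentrality
d·√(n₁n₂/(n₁+n₂)) and pooled df.

## Synthetic corpus generator

Each group is generated sentence-by-sentence: the first sentence draws a
topic uniformly from k = 20 topics (60 unique pseudo-words each); every
subsequent sentence keeps the topic with probability 1 − drift, else
resamples.  Tokens mix topic words with a shared real-English function-word
pool (40% function words), so even at drift = 1 consecutive sentences share
function words and expected coherence stays above zero, as in real text.
Valence and subjectivity are injected by swapping one token per sentence
(rate 0.6) for a lexicon word whose polarity/subjectivity lie within ±0.3 of
the group biases — a window wide enough that measured sentiment varies
across posts rather than collapsing to a constant design column, while its
breadth keeps sentiment injection essentially orthogonal to coherence.
Sentence counts are log-normal (default median 8, σ = 0.85, matching the
right-skewed post-length distributions typical of mental-health forums);
sentence lengths are normal (default 18 ± 6 words, clipped at 3).  All
randomness flows from per-group seeds expanded per post via SeedSequence, so
corpora are byte-identical across runs and platforms.  Generated posts are
guaranteed to survive filtration (terminal punctuation, capitalised
openers, no URLs, ≥ 2 sentences); `inject_artifacts` then corrupts seeded
disjoint subsets (removal placeholders, URLs, one-sentence truncation) to
exercise the filters.

What the generator does *not* emulate: grammatical structure, synonymy,
discourse markers, user-level clustering (several posts per author with
correlated style), topic mixtures within a sentence, or bot-generated text.
Passing the simulation studies therefore demonstrates that the pipeline
recovers vocabulary-mediated coherence structure and adjusts linear
confounds correctly; it does not certify performance of the hashing encoder
on natural language, where a pretrained encoder should be preferred.

## Simulation studies and problem sizes

The validation studies run at desk scale by the package's own choice of
conditions, stated here once:

* simulated posts in the studies use a compact shape (log-normal sentence
  count, median 4, σ 0.45 — median 3, σ 0.35 for the null study — and 7–8 ± 2–2.5
  words per sentence), since the properties under test (ordering, sign,
  calibration, partition) do not depend on post length;
* drift monotonicity: one 2,000-post arm per drift ∈ {0, .25, .5, .75, 1},
  encoder d = 512; strict decrease required across all adjacent arms;
* effect recovery: 100 replicates of drift .2 vs .6 at 2,000 posts/arm,
  d = 512; the covariate-adjusted contrast must be correctly signed with
  p < .001 in ≥ 95% of replicates;
* confound adjustment: 200 replicates of equal drift (.4) with unequal
  valence bias (0 vs .3), sentence length (7 vs 9 words) and post length
  (median 4 vs 5), 400 posts/arm, d = 512; the adjusted contrast must be
  non-significant at α = .05 in ≥ 90% of replicates, and the adjusted |d| is
  attenuated relative to the raw standardized difference;
* null calibration: 1,000 replicates of 5 identical groups × 500 posts with
  a 16-dim encoder (type-I behaviour is exchangeability-driven and does not
  depend on embedding width); the family-wise rate of any Tukey-adjusted
  p < .05 must not exceed .06;
* power: the closed form is checked against a 10⁵-draw Monte-Carlo of the
  noncentral t sampling distribution, and at group sizes 27,422 / 242,233
  with d = 0.255 it exceeds 0.999.

## Numerical choices and degenerate inputs

QR (not normal equations) for the fit; rank tolerance max(n,p)·ε·max|R_ii|,
with offending columns named on failure.  Tukey p-values are clipped to
[0, 1]; survival values below ~10⁻¹⁴ are limited by the 1 − CDF formulation,
which is immaterial at the .05/.001 decision thresholds.  Coherence of posts
is exactly bounded by the extreme consecutive-pair inner products.  Empty
corpora produce empty tables and zeroed reports, not errors; a one-sentence
post reaching the scorer raises.  Scored tables round-trip at 12 significant
digits.  Months for cohort sampling are UTC calendar months.

## Design choices on genuinely open points

* No deduplication of crossposts/reposts is performed (handling is
  unspecified in the source procedure; deduplication would require a
  similarity threshold that itself needs validation).
* Monthly user-sampled cohorts recruit from submissions only, and an author
  recruited by several group forums in one month is attributed to the
  alphabetically first and their posts returned once.
* EMM covariate grand means are taken over the model's own estimation
  sample (for a two-group model, the two-group subsample).
* The significance threshold is .05 throughout; with very large samples,
  effect sizes should carry the interpretive weight.

## Known limitations

User-level clustering is ignored (posts are treated as independent; a
mixed-effects extension is out of scope), the hashing encoder measures
surface overlap rather than meaning, the sentiment lexicon is compact
(~400 entries) and English-only, and the `.zst` input path requires the
optional `zstandard` module.
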