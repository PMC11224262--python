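# semcoh — semantic coherence analysis of forum posts

`semcoh` measures **speech coherence** in written forum posts and compares it
across groups of posters while adjusting for text covariates.  Reduced speech
coherence — weakened flow of meaning between consecutive sentences — is a
computational marker of formal thought disorder (tangentiality, derailment)
and is of interest for digital phenotyping of psychosis-spectrum conditions
from public social-media text.  The package is aimed at computational
psychiatry and clinical NLP researchers who want an inspectable, fully
offline implementation of this analysis, from raw post dumps to
covariate-adjusted group contrasts.

## The statistic

A post is segmented into sentences *s₁ … sₙ* (n ≥ 2), each sentence is mapped
to a unit-norm embedding *eᵢ* ∈ ℝᵈ (d = 512 by default), and coherence is the
mean inner product over consecutive pairs:

```
coherence = 1/(n−1) · Σᵢ ⟨eᵢ, eᵢ₊₁⟩        ∈ [−1, 1]
```

Group differences are tested with an OLS model

```
coherence ~ group + word_count + sentence_count + sentence_length
                  + valence + subjectivity
```

with a dummy-coded group factor; group effects are summarised as **estimated
marginal means** (model predictions with covariates at their grand means),
compared pairwise with **Tukey-adjusted** p-values from the studentized range
distribution, and standardised as **Cohen's d** (EMM difference / residual
SD).  Welch two-sample t-tests, partial η², adjusted R² and post-hoc power
(noncentral t) round out the inferential layer.

Because no pretrained weights ship with the package, the default encoder is a
deterministic feature-hashing encoder (word unigrams + character trigrams,
signed hashed coordinates, L2-normalised).  Pretrained universal sentence
encoders can be plugged in through the encoder registry; the analysis code is
agnostic to the encoder behind the unit-norm contract.

A seed-deterministic synthetic corpus generator with controllable
**topic drift** (the probability that consecutive sentences switch topic —
the ground-truth inverse of coherence), post-length distributions, valence
and subjectivity makes the entire pipeline testable offline and lets known
effect sizes be recovered end to end.

## Worked example

```python
from semcoh import (GroupSpec, HashingEncoder, CoherenceModel,
                    generate_corpus, score_posts)

specs = [
    GroupSpec("support",  n_posts=1000, drift=0.2, sentence_count_median=5,
              sentence_length_mean=10, valence_bias=-0.2, seed=1),
    GroupSpec("psychosis", n_posts=1000, drift=0.6, sentence_count_median=4,
              sentence_length_mean=9, valence_bias=0.0, seed=2),
]
posts = generate_corpus(specs)
scored, report = score_posts(posts, HashingEncoder(dim=512))
print(f"{report.n_surviving}/{report.n_input} posts survive filtration")
results = CoherenceModel.from_dataframe(scored, reference_group="support").fit()
print(results.summary())
```

prints

```
2000/2000 posts survive filtration
OLS group-comparison model
==============================================================================
N obs: 2000    residual df: 1993    sigma: 0.0587814
R^2: 0.1454    adj. R^2: 0.1428
reference group: support
------------------------------------------------------------------------------
term                            coef          se         t           p   eta2p
Intercept                   0.027583     0.00905      3.05     0.00232  0.0046
group[psychosis]           -0.013798     0.00365     -3.78    0.000159  0.0071
word_count                0.00021551    0.000146      1.48       0.139  0.0011
sentence_count            -0.0022799     0.00147     -1.55       0.121  0.0012
sentence_length            0.0071223    0.000739      9.64    1.54e-21  0.0446
valence                   -0.0046975      0.0106     -0.44       0.658  0.0001
subjectivity               -0.013484      0.0103     -1.31       0.191  0.0009
------------------------------------------------------------------------------
Estimated marginal means (covariates at grand means):
  psychosis            0.07932 [SE 0.00225]
  support              0.09311 [SE 0.00225]
Tukey-adjusted pairwise contrasts:
  psychosis - support: diff -0.01380 (SE 0.00365), t -3.78, p 0.000159, d -0.235 [-0.356, -0.113]
```

The high-drift ("psychosis") group writes measurably less coherent posts:
its estimated marginal mean is 0.079 vs 0.093, a covariate-adjusted Cohen's
d of −0.235 with a Tukey-adjusted p < .001 — the drift effect built into the
generator, recovered through the full pipeline.

The same analysis runs on real JSON-lines submission dumps (Pushshift field
names; plain, `.gz`, or `.zst` with the optional `zstandard` module), either
through the library (`read_posts` → `score_posts` → `CoherenceModel`) or the
CLI:

```
semcoh simulate --spec groups.json --out corpus.jsonl --seed 1
semcoh score    --input corpus.jsonl --out scored.tsv --dim 512
semcoh analyze  --scored scored.tsv --out-dir analysis/
semcoh run-all  --config run.json
```

## Layout

| module | role |
| --- | --- |
| `semcoh.corpus` | read/filter/write post records; monthly user-sampled cohorts |
| `semcoh.segmentation` | abbreviation-aware sentence segmentation |
| `semcoh.embedding` | encoder contract, hashing encoder, pretrained adapter slot |
| `semcoh.coherence` | the per-post coherence statistic |
| `semcoh.features` | word/sentence counts, lexicon valence and subjectivity |
| `semcoh.stats` | OLS model/results, EMMs, Tukey contrasts, t-tests, power |
| `semcoh.synthetic` | topic-drift corpus generator, artifact injection |
| `semcoh.pipeline` / `semcoh.cli` | end-to-end runs, manifests, command line |
| `semcoh.experiments` | simulation studies (calibration, recovery, monotonicity) |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
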