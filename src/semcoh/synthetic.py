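"""Synthetic forum corpora with controllable topic drift.

The generator emulates groups ("subreddits") of paragraph posts whose
between-sentence semantic similarity, length distributions, valence and
subjectivity are controlled per group, so the whole pipeline is testable
offline and known effect sizes are recoverable.

The generative mechanism for coherence is topic resampling: each post draws
an initial topic uniformly from a topic model; every subsequent sentence
keeps the current topic with probability ``1 - drift`` and resamples
uniformly otherwise.  Sentences are bags of topic words plus shared
function words, so sentence-level semantics are carried entirely by
vocabulary overlap — which a surface-feature encoder detects — and
``drift`` is the ground-truth inverse of coherence.  A shared function-word
pool keeps expected coherence above zero even at drift 1, as in real text.
Valence and subjectivity are injected by swapping in words from the shipped
sentiment lexicon whose polarity/subjectivity sit near the group's biases;
the injection pool is wide, so sentiment control has negligible effect on
between-sentence similarity.

All randomness flows from per-group seeds expanded per post through
``numpy``'s SeedSequence, so corpora are byte-identical across runs and
platforms regardless of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Post, RemovalState
from .features import SentimentLexicon, default_lexicon
from .segmentation import segment_sentences

__all__ = [
    "GroupSpec",
    "TopicModel",
    "default_topic_model",
    "generate_corpus",
    "inject_artifacts",
    "write_posts_jsonl",
]

#: fraction of tokens drawn from the shared function-word pool
FUNCTION_WORD_FRACTION = 0.4
#: per-sentence probability of swapping one token for a sentiment word
SENTIMENT_INJECTION_RATE = 0.6

_EPOCH_2023 = 1672531200  # 2023-01-01T00:00:00Z

# real English function words; sentiment-lexicon words, negators and
# intensifiers are deliberately absent so sentiment control stays exact
_FUNCTION_WORDS = (
    "the a an and of to in on at it is was were are be been am i you he she "
    "we they them us me my your our their his her its that this these those "
    "with for as from by or if then than when while there here what which "
    "who whom how because about into over under again once during after "
    "before both each few more most other some such only own same just also "
    "did does do has have had having would could should may might must shall "
    "will went goes going being between through against along around"
).split()


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters of one group ("subreddit") of posts.

    ``drift`` is the probability that the topic resamples between
    consecutive sentences; ``sentence_count_median``/``sigma`` are the
    log-normal median and dispersion of sentences per post;
    ``sentence_length_mean``/``sd`` are per-sentence word counts.
    Defaults mirror a mid-sized personal-narrative forum: a median of ~8
    sentences with heavy right skew, ~18 words per sentence, neutral tone,
    half-subjective wording.
    """

    group_name: str
    n_posts: int
    drift: float = 0.3
    sentence_count_median: float = 8.0
    sentence_count_sigma: float = 0.85
    sentence_length_mean: float = 18.0
    sentence_length_sd: float = 6.0
    valence_bias: float = 0.0
    subjectivity_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_posts < 1:
            raise ValueError("n_posts must be >= 1")
        if not 0.0 <= self.drift <= 1.0:
            raise ValueError("drift must lie in [0, 1]")
        if self.sentence_count_median < 2:
            raise ValueError("sentence_count_median must be >= 2")
        if self.sentence_length_mean < 3:
            raise ValueError("sentence_length_mean must be >= 3")
        if not -1.0 <= self.valence_bias <= 1.0:
            raise ValueError("valence_bias must lie in [-1, 1]")
        if not 0.0 <= self.subjectivity_bias <= 1.0:
            raise ValueError("subjectivity_bias must lie in [0, 1]")


@dataclass(frozen=True)
class TopicModel:
    """Disjoint-leaning topic vocabularies plus a shared function-word pool."""

    topic_words: tuple[tuple[str, ...], ...]
    function_words: tuple[str, ...]

    def __post_init__(self) -> None:
        for i, words in enumerate(self.topic_words):
            if len(set(words)) < 50:
                raise ValueError(f"topic {i} must offer >= 50 distinct words")

    @property
    def k_topics(self) -> int:
        return len(self.topic_words)


def _pseudo_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """Pronounceable pseudo-words, globally unique and lexicon-free."""
    onsets = list("bcdfghjklmnprstvz") + ["br", "cr", "dr", "fr", "gr", "pl", "st", "tr"]
    vowels = list("aeiou")
    words: list[str] = []
    while len(words) < n:
        k = int(rng.integers(2, 4))  # 2-3 syllables
        w = "".join(
            onsets[int(rng.integers(len(onsets)))] + vowels[int(rng.integers(len(vowels)))]
            for _ in range(k)
        )
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


_TOPIC_MODEL_CACHE: dict[tuple[int, int, int], TopicModel] = {}


def default_topic_model(
    k_topics: int = 20, words_per_topic: int = 60, seed: int = 7
) -> TopicModel:
    """Deterministic topic model with globally unique pseudo-word vocabularies."""
    key = (k_topics, words_per_topic, seed)
    cached = _TOPIC_MODEL_CACHE.get(key)
    if cached is not None:
        return cached
    lex = default_lexicon()
    reserved = set(_FUNCTION_WORDS) | set(lex.entries) | set(lex.negators) | set(lex.intensifiers)
    taken = set(reserved)
    topics = []
    for t in range(k_topics):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(t,)))
        topics.append(tuple(_pseudo_words(rng, words_per_topic, taken)))
    model = TopicModel(topic_words=tuple(topics), function_words=tuple(_FUNCTION_WORDS))
    _TOPIC_MODEL_CACHE[key] = model
    return model


def _sentiment_pool(lexicon: SentimentLexicon, valence: float, subjectivity: float) -> list[str]:
    """Lexicon words near the requested (polarity, subjectivity) point.

    The window is wide enough that drawn polarities vary around the bias,
    so measured valence varies across posts instead of collapsing to a
    constant column in the downstream design matrix.
    """
    tol_p, tol_s = 0.3, 0.3
    while True:
        pool = [
            w
            for w, (p, s) in lexicon.entries.items()
            if abs(p - valence) <= tol_p and abs(s - subjectivity) <= tol_s
        ]
        if len(pool) >= 15:
            return sorted(pool)
        tol_p += 0.05
        tol_s += 0.05


def _topic_arrays(topics: TopicModel) -> tuple[np.ndarray, np.ndarray]:
    """Function-word array and rectangular topic-word matrix for fast sampling.

    Ragged topic vocabularies are padded by cycling their own words, which
    keeps sampling uniform whenever the vocabularies are equal-sized (the
    default model) and near-uniform otherwise.
    """
    width = max(len(w) for w in topics.topic_words)
    rows = []
    for words in topics.topic_words:
        reps = -(-width // len(words))
        rows.append((list(words) * reps)[:width])
    return np.asarray(topics.function_words), np.asarray(rows)


def _generate_post(
    spec: GroupSpec,
    func_arr: np.ndarray,
    topic_mat: np.ndarray,
    pool: list[str],
    pool_width: int,
    rng: np.random.Generator,
    index: int,
) -> Post:
    k = topic_mat.shape[0]
    n_sent = max(
        2, int(round(spec.sentence_count_median * np.exp(spec.sentence_count_sigma * rng.standard_normal())))
    )
    lengths = np.maximum(
        3, np.round(rng.normal(spec.sentence_length_mean, spec.sentence_length_sd, n_sent))
    ).astype(int)
    # first-order Markov topic sequence: resample with probability drift
    topic_seq = np.empty(n_sent, dtype=np.intp)
    topic_seq[0] = rng.integers(k)
    resample = rng.random(n_sent - 1) < spec.drift
    fresh = rng.integers(k, size=n_sent - 1)
    for i in range(1, n_sent):
        topic_seq[i] = fresh[i - 1] if resample[i - 1] else topic_seq[i - 1]
    total = int(lengths.sum())
    is_function = rng.random(total) < FUNCTION_WORD_FRACTION
    func_idx = rng.integers(len(func_arr), size=total)
    word_idx = rng.integers(topic_mat.shape[1], size=total)
    inject = rng.random(n_sent) < SENTIMENT_INJECTION_RATE
    inject_word = rng.integers(len(pool), size=n_sent)
    inject_pos = rng.random(n_sent)  # scaled to sentence length below
    token_topic = np.repeat(topic_seq, lengths)
    tokens = np.where(is_function, func_arr[func_idx], topic_mat[token_topic, word_idx])
    if tokens.dtype.itemsize < 4 * pool_width:  # widen so injected words fit
        tokens = tokens.astype(f"<U{pool_width}")
    sentences: list[str] = []
    offset = 0
    for s in range(n_sent):
        L = int(lengths[s])
        toks = tokens[offset : offset + L]
        if inject[s]:
            toks[int(inject_pos[s] * L)] = pool[inject_word[s]]
        offset += L
        sentences.append(str(toks[0]).capitalize() + " " + " ".join(toks[1:]) + ".")
    return Post(
        post_id=f"{spec.group_name}-{index}",
        subreddit=spec.group_name,
        author=f"u_{spec.group_name}_{index % max(1, spec.n_posts // 3 or 1)}",
        title=f"post {index}",
        body=" ".join(sentences),
        created_utc=_EPOCH_2023 + 3600 * index,
        is_comment=False,
        removal_state=RemovalState.INTACT,
    )


def generate_corpus(
    specs: Sequence[GroupSpec],
    topics: TopicModel | None = None,
    lexicon: SentimentLexicon | None = None,
) -> list[Post]:
    """Generate posts for every group spec; seed-deterministic.

    Every generated post is an intact submission that survives the
    filtration rules (terminal punctuation, capitalized sentence openers,
    no URLs, >= 2 sentences).
    """
    if not specs:
        raise ValueError("at least one group spec required")
    if topics is None:
        topics = default_topic_model()
    if lexicon is None:
        lexicon = default_lexicon()
    func_arr, topic_mat = _topic_arrays(topics)
    posts: list[Post] = []
    for spec in specs:
        pool = _sentiment_pool(lexicon, spec.valence_bias, spec.subjectivity_bias)
        pool_width = max(len(w) for w in pool)
        seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_posts)
        for i in range(spec.n_posts):
            rng = np.random.default_rng(seeds[i])
            posts.append(_generate_post(spec, func_arr, topic_mat, pool, pool_width, rng, i))
    return posts


def inject_artifacts(
    posts: Sequence[Post],
    url_fraction: float = 0.0,
    short_fraction: float = 0.0,
    removed_fraction: float = 0.0,
    seed: int = 0,
) -> list[Post]:
    """Corrupt seeded random subsets of posts to exercise the filters.

    Disjoint subsets (expected sizes fraction * n) are replaced by a removal
    placeholder, given a URL, or truncated to a single sentence.
    """
    fractions = (removed_fraction, url_fraction, short_fraction)
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be >= 0")
    if sum(fractions) >= 1.0 + 1e-12:
        raise ValueError("fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    u = rng.random(len(posts))
    out: list[Post] = []
    from dataclasses import replace

    for post, ui in zip(posts, u):
        if ui < removed_fraction:
            out.append(replace(post, body="[removed]", removal_state=RemovalState.REMOVED))
        elif ui < removed_fraction + url_fraction:
            out.append(replace(post, body=post.body + " See https://example.com/more."))
        elif ui < removed_fraction + url_fraction + short_fraction:
            first = segment_sentences(post.body)[0]
            out.append(replace(post, body=first))
        else:
            out.append(post)
    return out


def write_posts_jsonl(posts: Sequence[Post], destination: str | Path) -> None:
    """Serialize posts in the JSON-lines dump dialect the reader accepts."""
    with Path(destination).open("w", encoding="utf-8") as fh:
        for p in posts:
            record = {
                "id": p.post_id,
                "subreddit": p.subreddit,
                "author": p.author,
                "title": p.title,
                "selftext": p.body,
                "created_utc": p.created_utc,
            }
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")
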