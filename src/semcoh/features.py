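"""Per-post text covariates: counts, length, valence, subjectivity.

Sentiment scoring is lexicon-based: every token that matches the shipped
word lexicon contributes its polarity (in [-1, 1]) and subjectivity (in
[0, 1]); the post-level valence and subjectivity are the means over matched
tokens (0 when nothing matches).  An immediately preceding intensifier
multiplies a match's polarity; a negation cue within a short preceding
window flips its sign and damps it (x -0.5 by default, the common
lexicon-scorer convention).  Subjectivity is unaffected by negation.

The lexicon ships as tab-separated ``word<TAB>polarity<TAB>subjectivity``
plus separate negator and intensifier lists, all user-replaceable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .segmentation import SentenceList

__all__ = [
    "ScoredPost",
    "SentimentLexicon",
    "load_lexicon",
    "default_lexicon",
    "count_words",
    "sentiment",
    "sentiment_from_tokens",
    "tokenize_words",
]

_WORD_TOKEN_RE = re.compile(r"[a-z0-9']+")

#: default negation behaviour (both configurable per call)
NEGATION_WINDOW = 3
NEGATION_FACTOR = -0.5


@dataclass(frozen=True)
class ScoredPost:
    """One row of the per-post feature table."""

    post_id: str
    group: str
    coherence: float
    word_count: int
    sentence_count: int
    sentence_length: float
    valence: float
    subjectivity: float

    def __post_init__(self) -> None:
        if self.sentence_count < 2:
            raise ValueError("a scored post has >= 2 sentences by construction")
        if not -1.0 <= self.valence <= 1.0:
            raise ValueError(f"valence {self.valence} outside [-1, 1]")
        if not 0.0 <= self.subjectivity <= 1.0:
            raise ValueError(f"subjectivity {self.subjectivity} outside [0, 1]")


@dataclass(frozen=True)
class SentimentLexicon:
    entries: dict[str, tuple[float, float]]  # word -> (polarity, subjectivity)
    negators: frozenset[str]
    intensifiers: dict[str, float]  # word -> multiplier > 0

    def __post_init__(self) -> None:
        for word, (pol, subj) in self.entries.items():
            if not -1.0 <= pol <= 1.0 or not 0.0 <= subj <= 1.0:
                raise ValueError(f"lexicon entry {word!r} out of range: {(pol, subj)}")
        for word, mult in self.intensifiers.items():
            if mult <= 0:
                raise ValueError(f"intensifier {word!r} multiplier must be > 0")

    def negate(self) -> "SentimentLexicon":
        """Copy with every polarity sign flipped (used in antisymmetry checks)."""
        return SentimentLexicon(
            entries={w: (-p, s) for w, (p, s) in self.entries.items()},
            negators=self.negators,
            intensifiers=dict(self.intensifiers),
        )


def _read_lines(text: str) -> Iterable[str]:
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            yield line


def load_lexicon(
    lexicon_path: str | Path,
    negators_path: str | Path | None = None,
    intensifiers_path: str | Path | None = None,
) -> SentimentLexicon:
    """Load a lexicon from TSV files (word, polarity, subjectivity)."""
    entries: dict[str, tuple[float, float]] = {}
    for line in _read_lines(Path(lexicon_path).read_text(encoding="utf-8")):
        word, pol, subj = line.split("\t")
        entries[word.lower()] = (float(pol), float(subj))
    negators: frozenset[str] = frozenset()
    if negators_path is not None:
        negators = frozenset(
            w.lower() for w in _read_lines(Path(negators_path).read_text(encoding="utf-8"))
        )
    intensifiers: dict[str, float] = {}
    if intensifiers_path is not None:
        for line in _read_lines(Path(intensifiers_path).read_text(encoding="utf-8")):
            word, mult = line.split("\t")
            intensifiers[word.lower()] = float(mult)
    return SentimentLexicon(entries=entries, negators=negators, intensifiers=intensifiers)


_DEFAULT_LEXICON: SentimentLexicon | None = None


def default_lexicon() -> SentimentLexicon:
    """The lexicon shipped with the package (cached)."""
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        data = resources.files("semcoh.data")
        entries: dict[str, tuple[float, float]] = {}
        for line in _read_lines(data.joinpath("sentiment_lexicon.tsv").read_text(encoding="utf-8")):
            word, pol, subj = line.split("\t")
            entries[word.lower()] = (float(pol), float(subj))
        negators = frozenset(
            w.lower() for w in _read_lines(data.joinpath("negators.txt").read_text(encoding="utf-8"))
        )
        intensifiers: dict[str, float] = {}
        for line in _read_lines(data.joinpath("intensifiers.tsv").read_text(encoding="utf-8")):
            word, mult = line.split("\t")
            intensifiers[word.lower()] = float(mult)
        _DEFAULT_LEXICON = SentimentLexicon(
            entries=entries, negators=negators, intensifiers=intensifiers
        )
    return _DEFAULT_LEXICON


def tokenize_words(sentence: str) -> list[str]:
    """Lowercased word tokens of one sentence (apostrophes kept)."""
    return _WORD_TOKEN_RE.findall(sentence.lower())


_HAS_ALNUM = re.compile(r"\w", re.UNICODE)


def count_words(sentences: SentenceList | Sequence[str]) -> int:
    """Whitespace-delimited word tokens across sentences, punctuation-only
    tokens excluded."""
    has_alnum = _HAS_ALNUM.search
    total = 0
    for sentence in sentences:
        total += sum(1 for token in sentence.split() if has_alnum(token))
    return total


def sentiment_from_tokens(
    token_lists: Sequence[Sequence[str]],
    lexicon: SentimentLexicon,
    *,
    negation_window: int = NEGATION_WINDOW,
    negation_factor: float = NEGATION_FACTOR,
) -> tuple[float, float]:
    """Valence and subjectivity from pre-tokenized sentences of one post.

    Negation and intensifier windows never cross sentence boundaries.
    """
    entries = lexicon.entries
    negators = lexicon.negators
    intensifiers = lexicon.intensifiers
    pol_sum = 0.0
    subj_sum = 0.0
    n_matched = 0
    for tokens in token_lists:
        for i, tok in enumerate(tokens):
            entry = entries.get(tok)
            if entry is None:
                continue
            pol, subj = entry
            if i > 0:
                mult = intensifiers.get(tokens[i - 1])
                if mult is not None:
                    pol *= mult
            lo = max(0, i - negation_window)
            if any(t in negators for t in tokens[lo:i]):
                pol *= negation_factor
            pol_sum += pol
            subj_sum += subj
            n_matched += 1
    if n_matched == 0:
        return 0.0, 0.0
    valence = min(1.0, max(-1.0, pol_sum / n_matched))
    subjectivity = min(1.0, max(0.0, subj_sum / n_matched))
    return valence, subjectivity


def sentiment(
    sentences: SentenceList | Sequence[str],
    lexicon: SentimentLexicon | None = None,
    *,
    negation_window: int = NEGATION_WINDOW,
    negation_factor: float = NEGATION_FACTOR,
) -> tuple[float, float]:
    """Post-level (valence, subjectivity) from raw sentences."""
    if lexicon is None:
        lexicon = default_lexicon()
    return sentiment_from_tokens(
        [tokenize_words(s) for s in sentences],
        lexicon,
        negation_window=negation_window,
        negation_factor=negation_factor,
    )
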