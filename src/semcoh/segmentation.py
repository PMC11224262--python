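"""Abbreviation-aware sentence segmentation.

Forum-post bodies are split into ordered sentences with explicit punctuation
rules rather than a trained model, so the segmentation contract is fully
inspectable and user-extendable:

* a run of terminal punctuation (``.``, ``!``, ``?``, ellipsis) ends a
  sentence when it is followed by whitespace and a capital letter (or digit),
  or by end of text;
* entries of a shipped abbreviation whitelist (``Dr.``, ``e.g.`` ...) and
  single-capital initials (``A.``) never end a sentence;
* a period between digits (``3.5 mg``) is never terminal;
* hard newlines end a sentence whenever the preceding fragment contains at
  least one word token — forum posts frequently omit terminal punctuation at
  line ends.

The whitelist ships as ``data/abbreviations.txt`` (one entry per line, ``#``
comments) and can be replaced or extended by the caller.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["SentenceList", "load_abbreviations", "default_abbreviations", "segment_sentences"]

_WORD_RE = re.compile(r"\w", re.UNICODE)

# candidate boundary: terminal punctuation run (ellipsis included), optional
# closing quotes/brackets, then either whitespace+capital/digit or end of text
_BOUNDARY_RE = re.compile(
    r"""(?P<punct>(?:\.{3}|…|[.!?])[.!?…]*)
        (?P<close>["'”’)\]]*)
        (?=(?P<tail>\s+["'“‘(\[]*[A-Z0-9]|\s*$))""",
    re.VERBOSE,
)

_SINGLE_INITIAL_RE = re.compile(r"(?:^|[\s(\[\"'“‘])[A-Z]\.$")
_DIGIT_PERIOD_RE = re.compile(r"\d\.$")


def load_abbreviations(path: str | Path) -> frozenset[str]:
    """Load an abbreviation whitelist file: one entry per line, '#' comments."""
    entries: set[str] = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            entries.add(line)
    return frozenset(entries)


_DEFAULT_ABBREVIATIONS: frozenset[str] | None = None


def default_abbreviations() -> frozenset[str]:
    """Whitelist shipped with the package (cached)."""
    global _DEFAULT_ABBREVIATIONS
    if _DEFAULT_ABBREVIATIONS is None:
        ref = resources.files("semcoh.data").joinpath("abbreviations.txt")
        entries: set[str] = set()
        for raw in ref.read_text(encoding="utf-8").splitlines():
            line = raw.split("#", 1)[0].strip()
            if line:
                entries.add(line)
        _DEFAULT_ABBREVIATIONS = frozenset(entries)
    return _DEFAULT_ABBREVIATIONS


@dataclass(frozen=True)
class SentenceList:
    """Ordered sentences of one post body."""

    sentences: tuple[str, ...]
    source_post_id: str = ""

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def __getitem__(self, i):
        return self.sentences[i]


def _is_protected(prefix: str, punct: str, abbreviations: frozenset[str]) -> bool:
    """True if the punctuation run ending ``prefix`` must not split.

    ``prefix`` is the text up to and including the punctuation run.
    """
    if punct not in (".",):
        return False  # only lone periods participate in abbreviations
    # period between digits is decimal, but the boundary regex already requires
    # whitespace after, so "3.5" never reaches here; "3." at a genuine sentence
    # end ("I took 3.") should split, except when part of an enumeration token.
    last = prefix.rsplit(None, 1)[-1] if prefix.split() else prefix
    # strip any opening quotes/brackets glued to the token
    last = last.lstrip("\"'“‘([")
    if last in abbreviations:
        return True
    if len(last) == 2 and last[0].isupper() and last[1] == ".":
        return True  # single-capital initial, "A."
    return False


def _split_fragment(fragment: str, abbreviations: frozenset[str]) -> list[str]:
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(fragment):
        end = m.end("close") if m.group("close") else m.end("punct")
        prefix = fragment[start : m.end("punct")]
        if _is_protected(prefix, m.group("punct"), abbreviations):
            continue
        piece = fragment[start:end].strip()
        if piece and _WORD_RE.search(piece):
            sentences.append(piece)
            start = end
    tail = fragment[start:].strip()
    if tail and _WORD_RE.search(tail):
        sentences.append(tail)
    return sentences


def segment_sentences(
    text: str,
    *,
    abbreviations: frozenset[str] | None = None,
    source_post_id: str = "",
) -> SentenceList:
    """Split ``text`` into sentences.

    Empty or whitespace-only text yields an empty :class:`SentenceList`.
    """
    if abbreviations is None:
        abbreviations = default_abbreviations()
    sentences: list[str] = []
    if text and text.strip():
        # hard newlines always terminate a sentence fragment
        for fragment in re.split(r"\n+", text):
            if fragment.strip():
                sentences.extend(_split_fragment(fragment, abbreviations))
    return SentenceList(sentences=tuple(sentences), source_post_id=source_post_id)
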