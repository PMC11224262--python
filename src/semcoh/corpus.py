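"""Reading, filtering and writing forum-post records.

Input is the JSON-lines dump dialect used by public Reddit submission
archives: one object per line with at least ``subreddit`` and a body-text
field (``selftext`` for submissions, ``body`` for comments), plus
``author``, ``title`` and ``created_utc``.  Plain, gzip- and (when the
optional ``zstandard`` module is available) zstd-compressed sources are
accepted.

Inclusion filters mirror the analysis contract and are applied in a fixed
order so exclusion counts partition the input exactly:

1. removed / deleted / empty bodies,
2. bodies containing a URL,
3. bodies that segment into fewer than two sentences.

Only the body text is ever evaluated; titles never substitute for bodies.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import SentenceList, segment_sentences

__all__ = [
    "Post",
    "RemovalState",
    "FilterReport",
    "read_posts",
    "filter_posts",
    "contains_url",
    "sample_generalization_cohort",
    "write_scored_table",
    "read_scored_table",
    "SCORED_COLUMNS",
]

logger = logging.getLogger(__name__)

REMOVAL_PLACEHOLDERS = {"[removed]", "[deleted]"}

SCORED_COLUMNS = [
    "post_id",
    "group",
    "coherence",
    "word_count",
    "sentence_count",
    "sentence_length",
    "valence",
    "subjectivity",
]


class RemovalState(str, Enum):
    INTACT = "intact"
    REMOVED = "removed"
    DELETED = "deleted"


@dataclass(frozen=True)
class Post:
    """One raw forum submission (or comment) record."""

    post_id: str
    subreddit: str
    author: str = ""
    title: str = ""
    body: str = ""
    created_utc: int = 0
    is_comment: bool = False
    removal_state: RemovalState = RemovalState.INTACT
    cohort: str | None = None  # group forum that recruited this post's author

    @property
    def group(self) -> str:
        return self.cohort if self.cohort is not None else self.subreddit


@dataclass(frozen=True)
class FilterReport:
    """Exclusion tallies; categories partition the input by first failing rule."""

    n_input: int
    n_removed_or_empty: int
    n_url: int
    n_too_short: int
    n_surviving: int

    def __post_init__(self) -> None:
        parts = self.n_removed_or_empty + self.n_url + self.n_too_short + self.n_surviving
        if parts != self.n_input:
            raise ValueError(f"filter categories {parts} do not partition n_input {self.n_input}")


def _removal_state(body: str) -> RemovalState:
    stripped = body.strip()
    if stripped == "[removed]":
        return RemovalState.REMOVED
    if stripped == "[deleted]":
        return RemovalState.DELETED
    if not stripped:
        # empty-after-trim carries no text; classed with removed placeholders
        return RemovalState.REMOVED
    return RemovalState.INTACT


def _open_source(source) -> io.TextIOBase | Iterable[str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        name = path.name.lower()
        if name.endswith(".gz"):
            return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
        if name.endswith(".zst"):
            try:
                import zstandard  # type: ignore[import-not-found]
            except ImportError as exc:
                raise ImportError(
                    "reading .zst sources requires the optional 'zstandard' module"
                ) from exc
            fh = zstandard.ZstdDecompressor(max_window_size=2**31).stream_reader(
                path.open("rb")
            )
            return io.TextIOWrapper(fh, encoding="utf-8")
        return path.open("r", encoding="utf-8")
    return source  # already an iterable of lines / open text handle


def _record_to_post(record: dict, lineno: int) -> Post:
    subreddit = record["subreddit"]
    is_comment = bool(record.get("is_comment", False))
    if "selftext" in record or "title" in record:
        body = record.get("selftext", "") or ""
    elif "body" in record:
        # comment-shaped record: body field, no title/selftext structure
        body = record.get("body", "") or ""
        is_comment = True
    else:
        raise KeyError("record has neither selftext/title nor body")
    return Post(
        post_id=str(record.get("id", record.get("post_id", f"line{lineno}"))),
        subreddit=str(subreddit),
        author=str(record.get("author", "") or ""),
        title=str(record.get("title", "") or ""),
        body=str(body),
        created_utc=int(record.get("created_utc", 0) or 0),
        is_comment=is_comment,
        removal_state=_removal_state(str(body)),
    )


def read_posts(source) -> tuple[list[Post], int]:
    """Read posts from a JSON-lines source.

    ``source`` may be a path (optionally .gz / .zst) or any iterable of
    lines.  Malformed lines are skipped with a logged warning; the count of
    skipped lines is returned alongside the posts.  An unreadable source
    raises (OSError / ImportError).
    """
    handle = _open_source(source)
    posts: list[Post] = []
    n_malformed = 0
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                if not isinstance(record, dict):
                    raise TypeError("record is not an object")
                posts.append(_record_to_post(record, lineno))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                n_malformed += 1
                logger.warning("skipping malformed record at line %d: %s", lineno, exc)
    finally:
        if isinstance(handle, io.TextIOBase):
            handle.close()
    if n_malformed:
        logger.warning("skipped %d malformed record(s)", n_malformed)
    return posts, n_malformed


# URL detection: scheme-based plus bare domains with a recognized TLD.
_COMMON_TLDS = (
    "com|org|net|edu|gov|mil|int|io|co|uk|de|fr|ca|au|us|ru|jp|cn|in|br|it|nl|es|se|no|"
    "info|biz|me|tv|ly|gg|fm|app|dev|ai|xyz|site|online|blog|shop|wiki|life|world|news"
)
_URL_RE = re.compile(
    r"""(?:(?:https?|ftp)://\S+)
      | (?:\bwww\.[a-z0-9-]+(?:\.[a-z0-9-]+)+\S*)
      | (?:\b[a-z0-9][a-z0-9-]*(?:\.[a-z0-9][a-z0-9-]*)*\.(?:%s)(?:/\S*)?(?=[\s),.!?;:'"]|$))
    """ % _COMMON_TLDS,
    re.IGNORECASE | re.VERBOSE,
)


def contains_url(text: str) -> bool:
    """Scheme-based or bare-domain URL detection."""
    return _URL_RE.search(text) is not None


def filter_posts(
    posts: Sequence[Post],
    segmenter: Callable[[str], SentenceList] = segment_sentences,
) -> tuple[list[Post], FilterReport]:
    """Apply the inclusion rules in fixed order; returns survivors + report.

    Each post is counted once, at the first rule it fails:
    removed/deleted/empty -> contains URL -> fewer than two sentences.
    """
    survivors: list[Post] = []
    n_removed = n_url = n_short = 0
    for post in posts:
        if post.removal_state is not RemovalState.INTACT or not post.body.strip():
            n_removed += 1
            continue
        if contains_url(post.body):
            n_url += 1
            continue
        if len(segmenter(post.body)) < 2:
            n_short += 1
            continue
        survivors.append(post)
    report = FilterReport(
        n_input=len(posts),
        n_removed_or_empty=n_removed,
        n_url=n_url,
        n_too_short=n_short,
        n_surviving=len(survivors),
    )
    return survivors, report


def _month_key(created_utc: int) -> tuple[int, int]:
    dt = datetime.fromtimestamp(created_utc, tz=timezone.utc)
    return dt.year, dt.month


def _valid_author(author: str) -> bool:
    return bool(author) and author != "[deleted]"


def sample_generalization_cohort(
    posts: Sequence[Post],
    group_forums: set[str] | frozenset[str],
    excluded_forums: set[str] | frozenset[str],
    per_month_user_cap: int = 1000,
    rng_seed: int = 0,
) -> list[Post]:
    """Monthly user-sampling cohort for the generalization analysis.

    For each UTC calendar month, the authors submitting intact posts in each
    group forum are collected; if more than ``per_month_user_cap`` authors
    are found, that many are sampled uniformly without replacement (seeded).
    All of that month's intact submissions by sampled authors are returned,
    excluding posts made in ``excluded_forums``; each returned post is
    tagged (``cohort``) with the group forum that recruited its author.  An
    author recruited by several group forums in one month is attributed to
    the alphabetically first and returned once.
    """
    if per_month_user_cap < 1:
        raise ValueError("per_month_user_cap must be >= 1")
    rng = np.random.default_rng(rng_seed)
    # month -> forum -> set of recruiting authors
    recruits: dict[tuple[int, int], dict[str, set[str]]] = {}
    for post in posts:
        if post.is_comment or post.removal_state is not RemovalState.INTACT:
            continue
        if post.subreddit in group_forums:
            if not _valid_author(post.author):
                logger.warning("post %s has no usable author; cannot recruit", post.post_id)
                continue
            recruits.setdefault(_month_key(post.created_utc), {}).setdefault(
                post.subreddit, set()
            ).add(post.author)
    # month -> author -> attributed forum (deterministic iteration order)
    attribution: dict[tuple[int, int], dict[str, str]] = {}
    for month in sorted(recruits):
        month_attr: dict[str, str] = {}
        for forum in sorted(recruits[month]):
            authors = sorted(recruits[month][forum])
            if len(authors) > per_month_user_cap:
                picked = rng.choice(len(authors), size=per_month_user_cap, replace=False)
                authors = [authors[i] for i in sorted(picked)]
            for author in authors:
                month_attr.setdefault(author, forum)
        attribution[month] = month_attr
    cohort: list[Post] = []
    for post in posts:
        if post.is_comment or post.removal_state is not RemovalState.INTACT:
            continue
        if not post.body.strip() or post.subreddit in excluded_forums:
            continue
        if not _valid_author(post.author):
            continue
        forum = attribution.get(_month_key(post.created_utc), {}).get(post.author)
        if forum is not None:
            cohort.append(replace(post, cohort=forum))
    return cohort


def write_scored_table(rows, destination: str | Path, sep: str = "\t") -> None:
    """Write ScoredPost rows (or an equivalent DataFrame) as a delimited table.

    Values round-trip losslessly at 12 significant digits.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.loc[:, SCORED_COLUMNS]
    else:
        df = pd.DataFrame([vars(r) for r in rows], columns=SCORED_COLUMNS)
    df.to_csv(destination, sep=sep, index=False, float_format="%.12g")


def read_scored_table(source: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a table written by :func:`write_scored_table`."""
    return pd.read_csv(source, sep=sep, dtype={"post_id": str, "group": str})
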