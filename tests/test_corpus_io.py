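import gzip
import json

import numpy as np
import pandas as pd
import pytest

from semcoh.corpus import (
    FilterReport,
    Post,
    RemovalState,
    contains_url,
    filter_posts,
    read_posts,
    read_scored_table,
    sample_generalization_cohort,
    write_scored_table,
)
from semcoh.features import ScoredPost


def _jsonl(records):
    return [json.dumps(r) for r in records]


def test_read_posts_field_mapping():
    posts, bad = read_posts(
        _jsonl([{"subreddit": "schizophrenia", "selftext": "A. B.", "title": "t"}])
    )
    assert bad == 0
    (p,) = posts
    assert p.body == "A. B." and p.title == "t"
    assert not p.is_comment
    assert p.removal_state is RemovalState.INTACT


@pytest.mark.parametrize(
    "body, state",
    [("[removed]", RemovalState.REMOVED), ("[deleted]", RemovalState.DELETED),
     ("   ", RemovalState.REMOVED)],
)
def test_read_posts_removal_markers(body, state):
    posts, _ = read_posts(_jsonl([{"subreddit": "s", "selftext": body, "title": "t"}]))
    assert posts[0].removal_state is state


def test_read_posts_skips_malformed_lines():
    lines = _jsonl([{"subreddit": "a", "selftext": "One. Two.", "title": "x"}])
    lines += ["{not json", ""]
    lines += _jsonl([{"subreddit": "b", "selftext": "Three. Four.", "title": "y"}])
    posts, bad = read_posts(lines)
    assert len(posts) == 2
    assert bad == 1


def test_read_posts_comment_shaped_records():
    posts, _ = read_posts(_jsonl([{"subreddit": "s", "body": "a comment"}]))
    assert posts[0].is_comment


def test_read_posts_gzip(tmp_path):
    path = tmp_path / "dump.jsonl.gz"
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        fh.write(json.dumps({"subreddit": "s", "selftext": "One. Two.", "title": "t"}) + "\n")
    posts, bad = read_posts(path)
    assert len(posts) == 1 and bad == 0


def test_read_posts_unreadable_source_raises(tmp_path):
    with pytest.raises(OSError):
        read_posts(tmp_path / "missing.jsonl")


@pytest.mark.parametrize(
    "text, expected",
    [
        ("Visit http://x.y for info. Thanks.", True),
        ("See https://example.com/page too.", True),
        ("Check www.reddit.com please.", True),
        ("I bought it on amazon.com yesterday.", True),
        ("Plain text with e.g. nothing. More text.", False),
        ("I took 3.5 mg today.", False),
        ("My score was 10.5. Not bad.", False),
    ],
)
def test_url_detection(text, expected):
    assert contains_url(text) is expected


def _post(i, body, state=RemovalState.INTACT, sub="s", author="u", ts=1672531200):
    return Post(post_id=f"p{i}", subreddit=sub, author=author, body=body,
                created_utc=ts, removal_state=state)


def test_filter_order_and_partition():
    posts = [
        _post(0, "[deleted]", RemovalState.DELETED),
        _post(1, "Visit http://x.y for info. Thanks."),
        _post(2, "One sentence only."),
        _post(3, "Two sentences. Right here."),
    ]
    survivors, report = filter_posts(posts)
    assert [p.post_id for p in survivors] == ["p3"]
    assert report == FilterReport(4, 1, 1, 1, 1)


def test_filter_counts_first_failing_rule_only():
    # a removed post whose placeholder body is also one short sentence
    posts = [_post(0, "[removed]", RemovalState.REMOVED),
             _post(1, "Short with http://u.rl only.")]
    _, report = filter_posts(posts)
    assert (report.n_removed_or_empty, report.n_url, report.n_too_short) == (1, 1, 0)


def test_filter_is_idempotent(two_group_corpus):
    survivors, r1 = filter_posts(two_group_corpus)
    again, r2 = filter_posts(survivors)
    assert [p.post_id for p in again] == [p.post_id for p in survivors]
    assert r2.n_surviving == r1.n_surviving == r2.n_input


def test_empty_input_gives_zero_report():
    survivors, report = filter_posts([])
    assert survivors == [] and report.n_input == 0


JAN, FEB = 1672531200, 1675209600  # 2023-01-01, 2023-02-01 UTC


def test_cohort_keeps_all_when_under_cap():
    posts = [_post(i, "Two sent. Here now.", sub="mh", author=f"a{i}", ts=JAN) for i in range(5)]
    posts += [_post(10 + i, "Neutral post. Indeed.", sub="other", author=f"a{i}", ts=JAN)
              for i in range(5)]
    cohort = sample_generalization_cohort(posts, {"mh"}, {"mh"}, per_month_user_cap=1000)
    assert sorted(p.author for p in cohort) == [f"a{i}" for i in range(5)]
    assert all(p.cohort == "mh" and p.subreddit == "other" for p in cohort)


def test_cohort_excludes_excluded_forums_and_tags_group():
    posts = [
        _post(0, "Recruiting post. Yes.", sub="mh", author="alice", ts=JAN),
        _post(1, "Allowed post. Sure.", sub="hobby", author="alice", ts=JAN),
        _post(2, "Excluded post. Sadly.", sub="control", author="alice", ts=JAN),
        _post(3, "Wrong month. Post.", sub="hobby", author="alice", ts=FEB),
    ]
    cohort = sample_generalization_cohort(posts, {"mh"}, {"mh", "control"})
    assert [p.post_id for p in cohort] == ["p1"]
    assert cohort[0].cohort == "mh"
    assert cohort[0].group == "mh"


def test_cohort_cap_sampling_is_seeded_and_deterministic():
    posts = [_post(i, "Recruit here. Now.", sub="mh", author=f"a{i}", ts=JAN) for i in range(50)]
    posts += [_post(100 + i, "Other forum. Post.", sub="x", author=f"a{i}", ts=JAN)
              for i in range(50)]
    c1 = sample_generalization_cohort(posts, {"mh"}, {"mh"}, per_month_user_cap=10, rng_seed=3)
    c2 = sample_generalization_cohort(posts, {"mh"}, {"mh"}, per_month_user_cap=10, rng_seed=3)
    c3 = sample_generalization_cohort(posts, {"mh"}, {"mh"}, per_month_user_cap=10, rng_seed=4)
    assert [p.post_id for p in c1] == [p.post_id for p in c2]
    assert len({p.author for p in c1}) == 10
    assert [p.post_id for p in c1] != [p.post_id for p in c3]


def test_cohort_never_returns_excluded_forum_posts_fuzz():
    rng = np.random.default_rng(8)
    forums = ["mh1", "mh2", "ctrl", "hobby", "news"]
    posts = []
    for i in range(400):
        posts.append(
            _post(
                i,
                "Some text. More text.",
                sub=forums[rng.integers(len(forums))],
                author=f"a{rng.integers(40)}",
                ts=JAN + int(rng.integers(0, 90)) * 86400,
            )
        )
    excluded = {"mh1", "mh2", "ctrl"}
    cohort = sample_generalization_cohort(posts, {"mh1", "mh2"}, excluded, 7, rng_seed=1)
    assert cohort, "fuzz corpus should produce a nonempty cohort"
    assert all(p.subreddit not in excluded for p in cohort)


def test_cohort_deleted_author_cannot_recruit():
    posts = [
        _post(0, "Recruit attempt. Here.", sub="mh", author="[deleted]", ts=JAN),
        _post(1, "Other post. Yes.", sub="x", author="[deleted]", ts=JAN),
    ]
    assert sample_generalization_cohort(posts, {"mh"}, {"mh"}) == []


def test_scored_table_roundtrip(tmp_path):
    rows = [
        ScoredPost("p1", "g1", 0.123456789012, 10, 2, 5.0, -0.25, 0.5),
        ScoredPost("p2", "g2", -0.000123456789, 30, 3, 10.0, 0.75, 0.9),
    ]
    path = tmp_path / "scored.tsv"
    write_scored_table(rows, path)
    assert len(path.read_text().splitlines()) == 3  # header + 2 rows
    back = read_scored_table(path)
    assert list(back["post_id"]) == ["p1", "p2"]
    np.testing.assert_allclose(back["coherence"], [r.coherence for r in rows], rtol=1e-11)
    np.testing.assert_allclose(back["valence"], [r.valence for r in rows], rtol=1e-11)


def test_scored_table_empty_writes_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_scored_table([], path)
    lines = path.read_text().splitlines()
    assert len(lines) == 1
    assert lines[0].split("\t")[0] == "post_id"
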