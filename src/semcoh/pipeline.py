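"""End-to-end orchestration: ingest/generate -> filter -> score -> model.

:func:`score_posts` is the scoring engine: it applies the inclusion
filters, segments surviving posts, embeds all sentences in one batch,
computes per-post coherence and text covariates, and returns a tidy
DataFrame (one row per post) plus the filtration report.  The batched path
is numerically identical to calling the per-post operations one at a time.

:func:`run_pipeline` wraps the whole study around a :class:`RunConfig`:
corpus in (file or synthetic spec), scored table, model summary, EMM /
contrast table and a manifest (config hash, seed, stage counts, artifact
checksums) out.  Reruns with the same config and the built-in encoder
reproduce identical scored tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import corpus as corpus_io
from .coherence import batch_coherence
from .corpus import FilterReport, Post, read_posts, write_scored_table
from .embedding import Encoder, HashingEncoder
from .features import (
    SentimentLexicon,
    count_words,
    default_lexicon,
    sentiment_from_tokens,
    tokenize_words,
)
from .segmentation import default_abbreviations, load_abbreviations, segment_sentences
from .stats import ALPHA, CoherenceModel
from .synthetic import GroupSpec, generate_corpus, write_posts_jsonl

__all__ = ["score_posts", "RunConfig", "RunResult", "run_pipeline"]

logger = logging.getLogger(__name__)


def score_posts(
    posts: Sequence[Post],
    encoder: Encoder | None = None,
    lexicon: SentimentLexicon | None = None,
    *,
    abbreviations: frozenset[str] | None = None,
    sentence_length_mode: str = "ratio",
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter and score a corpus; one DataFrame row per surviving post.

    Columns: post_id, group, coherence, word_count, sentence_count,
    sentence_length, valence, subjectivity.  ``sentence_length_mode`` is
    either ``"ratio"`` (words / sentences per post, the default) or
    ``"mean_per_sentence"`` (mean of per-sentence word counts).
    """
    if encoder is None:
        encoder = HashingEncoder()
    if lexicon is None:
        lexicon = default_lexicon()
    if sentence_length_mode not in ("ratio", "mean_per_sentence"):
        raise ValueError("sentence_length_mode must be 'ratio' or 'mean_per_sentence'")
    submissions = [p for p in posts if not p.is_comment]
    n_comments = len(posts) - len(submissions)
    if n_comments:
        logger.info("ignoring %d comment records", n_comments)
    segmenter = (
        segment_sentences
        if abbreviations is None
        else (lambda text: segment_sentences(text, abbreviations=abbreviations))
    )
    # single pass: same rule order as filter_posts, segmenting each body once
    survivors: list[Post] = []
    sentence_lists = []
    all_sentences: list[str] = []
    count_list: list[int] = []
    n_removed = n_url = n_short = 0
    for post in submissions:
        if post.removal_state is not corpus_io.RemovalState.INTACT or not post.body.strip():
            n_removed += 1
            continue
        if corpus_io.contains_url(post.body):
            n_url += 1
            continue
        sentences = segmenter(post.body)
        if len(sentences) < 2:
            n_short += 1
            continue
        survivors.append(post)
        sentence_lists.append(sentences)
        all_sentences.extend(sentences)
        count_list.append(len(sentences))
    report = FilterReport(
        n_input=len(submissions),
        n_removed_or_empty=n_removed,
        n_url=n_url,
        n_too_short=n_short,
        n_surviving=len(survivors),
    )
    if not survivors:
        empty = pd.DataFrame(columns=corpus_io.SCORED_COLUMNS)
        return empty, report
    counts = np.asarray(count_list, dtype=np.intp)

    token_lists = [tokenize_words(s) for s in all_sentences]
    if hasattr(encoder, "encode_token_lists"):
        vectors = encoder.encode_token_lists(token_lists)  # fast path, same tokens
    else:
        vectors = np.asarray(encoder.encode(all_sentences), dtype=float)
    coherence = batch_coherence(vectors, counts)

    rows = []
    offset = 0
    for i, post in enumerate(survivors):
        n_sent = int(counts[i])
        sentences = sentence_lists[i]
        post_tokens = token_lists[offset : offset + n_sent]
        offset += n_sent
        wc = count_words(sentences)
        if sentence_length_mode == "ratio":
            slen = wc / n_sent
        else:
            per_sent = [
                sum(1 for t in s.split() if any(ch.isalnum() for ch in t)) for s in sentences
            ]
            slen = float(np.mean(per_sent))
        val, subj = sentiment_from_tokens(post_tokens, lexicon)
        rows.append(
            {
                "post_id": post.post_id,
                "group": post.group,
                "coherence": float(coherence[i]),
                "word_count": wc,
                "sentence_count": n_sent,
                "sentence_length": slen,
                "valence": val,
                "subjectivity": subj,
            }
        )
    return pd.DataFrame(rows), report


# ---------------------------------------------------------------------------
# run configuration and orchestration


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``input_path`` (JSON-lines corpus) or ``synthetic_groups``
    (list of GroupSpec field dicts) must be provided.
    """

    output_dir: str
    input_path: str | None = None
    synthetic_groups: list[dict] | None = None
    encoder_id: str = "hashing"
    dim: int = 512
    abbreviations_path: str | None = None
    lexicon_path: str | None = None
    negators_path: str | None = None
    intensifiers_path: str | None = None
    reference_group: str | None = None
    alpha: float = ALPHA
    sentence_length_mode: str = "ratio"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic_groups is None):
            raise ValueError("provide exactly one of input_path or synthetic_groups")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunResult:
    scored: pd.DataFrame
    filter_report: FilterReport
    summary_text: str | None
    emmeans: pd.DataFrame | None
    contrasts: pd.DataFrame | None
    manifest: dict
    output_dir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order and write every artifact plus a manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # stage: corpus
    if config.input_path is not None:
        posts, n_malformed = read_posts(config.input_path)
        logger.info("read %d posts (%d malformed lines skipped)", len(posts), n_malformed)
    else:
        specs = []
        for i, g in enumerate(config.synthetic_groups or []):
            g = dict(g)
            g.setdefault("seed", config.seed + i)
            specs.append(GroupSpec(**g))
        posts = generate_corpus(specs)
        n_malformed = 0
        write_posts_jsonl(posts, outdir / "corpus.jsonl")
        logger.info("generated %d synthetic posts in %d groups", len(posts), len(specs))

    encoder = HashingEncoder(dim=config.dim, seed=config.seed) if config.encoder_id == "hashing" else None
    if encoder is None:
        from .embedding import get_encoder

        encoder = get_encoder(config.encoder_id, dim=config.dim)
    abbreviations = (
        load_abbreviations(config.abbreviations_path)
        if config.abbreviations_path
        else default_abbreviations()
    )
    if config.lexicon_path:
        from .features import load_lexicon

        lexicon = load_lexicon(config.lexicon_path, config.negators_path, config.intensifiers_path)
    else:
        lexicon = default_lexicon()

    # stage: filter + score
    scored, report = score_posts(
        posts,
        encoder,
        lexicon,
        abbreviations=abbreviations,
        sentence_length_mode=config.sentence_length_mode,
    )
    write_scored_table(scored, outdir / "scored.tsv")
    (outdir / "filter_report.json").write_text(
        json.dumps(vars(report), indent=2) + "\n", encoding="utf-8"
    )

    # stage: model
    summary_text = None
    emmeans = contrasts = None
    n_groups = scored["group"].nunique() if len(scored) else 0
    if n_groups >= 2:
        model = CoherenceModel.from_dataframe(scored, reference_group=config.reference_group)
        results = model.fit()
        summary_text = results.summary()
        (outdir / "model_summary.txt").write_text(summary_text + "\n", encoding="utf-8")
        emmeans = results.emmeans()
        emmeans.to_csv(outdir / "emmeans.tsv", sep="\t", index=False, float_format="%.12g")
        contrasts = results.pairwise()
        contrasts.to_csv(outdir / "emm_contrasts.tsv", sep="\t", index=False, float_format="%.12g")
    else:
        logger.warning("fewer than two groups after filtration; skipping the model stage")

    artifacts = [p for p in ("corpus.jsonl", "scored.tsv", "filter_report.json",
                             "model_summary.txt", "emmeans.tsv", "emm_contrasts.tsv")
                 if (outdir / p).exists()]
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_counts": {
            "input_posts": len(posts),
            "malformed_lines": n_malformed,
            **vars(report),
            "modelled_groups": int(n_groups),
        },
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return RunResult(
        scored=scored,
        filter_report=report,
        summary_text=summary_text,
        emmeans=emmeans,
        contrasts=contrasts,
        manifest=manifest,
        output_dir=outdir,
    )
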