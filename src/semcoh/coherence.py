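"""Per-post semantic coherence.

Coherence is the mean inner product over consecutive sentence-embedding
pairs: for sentences with unit-norm embeddings e_1..e_n,

    coherence = (1 / (n - 1)) * sum_{i=1}^{n-1} <e_i, e_{i+1}>

Only first-order (adjacent) pairs enter; the statistic lies in [-1, 1] and
needs at least two sentences, which the filtration stage guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingSet

__all__ = ["CoherenceScore", "coherence_score", "batch_coherence"]


@dataclass(frozen=True)
class CoherenceScore:
    value: float
    n_pairs: int
    post_id: str = ""

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("coherence needs at least one consecutive pair")
        if not -1.0 - 1e-9 <= self.value <= 1.0 + 1e-9:
            raise ValueError(f"coherence {self.value} outside [-1, 1]")


def coherence_score(embeddings: EmbeddingSet, post_id: str = "") -> CoherenceScore:
    """Mean inner product of consecutive sentence embeddings of one post."""
    v = embeddings.vectors
    n = v.shape[0]
    if n < 2:
        raise ValueError(
            "coherence requires >= 2 sentences; a shorter post should have "
            "been excluded by filtration"
        )
    dots = np.einsum("ij,ij->i", v[:-1], v[1:])
    return CoherenceScore(value=float(dots.mean()), n_pairs=n - 1, post_id=post_id)


def batch_coherence(vectors: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Coherence for many posts whose sentence vectors are stacked row-wise.

    ``vectors`` holds all posts' sentence embeddings concatenated in post
    order; ``counts[j]`` is the number of sentences of post j (each >= 2).
    Returns one coherence value per post; numerically identical to calling
    :func:`coherence_score` per post.
    """
    counts = np.asarray(counts, dtype=np.intp)
    if np.any(counts < 2):
        raise ValueError("every post needs >= 2 sentences")
    if int(counts.sum()) != vectors.shape[0]:
        raise ValueError("counts do not partition the stacked vectors")
    dots = np.einsum("ij,ij->i", vectors[:-1], vectors[1:])
    # drop the dot products that straddle a post boundary
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    boundary = starts[1:] - 1  # index into dots of each straddling pair
    keep = np.ones(dots.shape[0], dtype=bool)
    keep[boundary] = False
    kept = dots[keep]
    # segment means over consecutive runs of (counts - 1) pair values
    pair_counts = counts - 1
    seg_starts = np.concatenate(([0], np.cumsum(pair_counts)[:-1]))
    sums = np.add.reduceat(kept, seg_starts)
    return sums / pair_counts
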