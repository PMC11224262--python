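"""Sentence encoders behind a pluggable contract.

Every encoder maps a batch of sentences to one unit-L2-norm vector per
sentence in a fixed dimension (default 512, matching widely used pretrained
universal sentence encoders).  Inner products between encoder outputs are
therefore cosines in [-1, 1], which is what the downstream coherence
statistic assumes.

Two encoders ship here:

``HashingEncoder``
    A deterministic, dependency-free encoder for offline use: the bag of
    lowercased word unigrams and character trigrams of a sentence, each
    feature hashed (seeded, via BLAKE2) to a signed coordinate, summed and
    L2-normalised.  Sentences sharing more surface features have a higher
    inner product in expectation; disjoint-vocabulary sentences are nearly
    orthogonal at dim 512.  Identical inputs produce bitwise-identical
    vectors on any platform.

``PretrainedSentenceEncoder``
    A lazy adapter for a TensorFlow-Hub universal sentence encoder.  It is
    optional, never exercised in the test suite, and never downloads weights
    implicitly at import time.

Additional encoders can be registered with :func:`register_encoder`; the
unit-norm / fixed-dim contract is checked at registration.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .segmentation import SentenceList

__all__ = [
    "EmbeddingSet",
    "Encoder",
    "HashingEncoder",
    "PretrainedSentenceEncoder",
    "register_encoder",
    "get_encoder",
    "available_encoders",
    "embed_sentences",
    "builtin_encode",
]

#: default hash seed; fixed so test vectors are reproducible across platforms
DEFAULT_HASH_SEED = 9001

_TOKEN_RE = re.compile(r"[a-z0-9']+")

_NORM_TOL = 1e-9


@runtime_checkable
class Encoder(Protocol):
    """Contract every sentence encoder satisfies."""

    encoder_id: str
    dim: int

    def encode(self, sentences: Sequence[str]) -> np.ndarray:  # (n, dim), unit rows
        ...


@dataclass(frozen=True)
class EmbeddingSet:
    """Ordered unit-norm sentence vectors for one post."""

    vectors: np.ndarray  # shape (n_sentences, dim)
    dim: int
    encoder_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != self.dim:
            raise ValueError(f"expected vectors of shape (n, {self.dim}), got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if not np.all(np.abs(norms - 1.0) < 1e-6):
            raise ValueError("embedding vectors must be unit L2 norm")
        object.__setattr__(self, "vectors", v)

    def __len__(self) -> int:
        return self.vectors.shape[0]


class HashingEncoder:
    """Deterministic feature-hashing sentence encoder.

    Features are lowercased word unigrams plus character trigrams of each
    word padded with ``<`` ``>`` boundary markers.  Each feature is hashed
    with a keyed BLAKE2b digest to a coordinate index and a sign; the signed
    unit contributions are summed and the result L2-normalised.  A sentence
    with no extractable features maps to the fixed basis vector e1.

    Parameters
    ----------
    dim : embedding dimension (>= 2); 512 by default.
    seed : hash key; changing it yields an unrelated random projection.
    """

    def __init__(self, dim: int = 512, seed: int = DEFAULT_HASH_SEED) -> None:
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = int(dim)
        self.seed = int(seed)
        self.encoder_id = f"hashing-{self.dim}-{self.seed}"
        self._key = self.seed.to_bytes(8, "little", signed=False)
        # token -> summed signed contribution of the token's features
        self._token_cache: dict[str, np.ndarray] = {}

    # -- feature machinery -------------------------------------------------

    def tokenize(self, sentence: str) -> list[str]:
        return _TOKEN_RE.findall(sentence.lower())

    def _hash_feature(self, feature: str) -> tuple[int, int]:
        h = int.from_bytes(
            hashlib.blake2b(feature.encode("utf-8"), digest_size=8, key=self._key).digest(),
            "little",
        )
        sign = 1 if h & (1 << 63) else -1
        return (h & ((1 << 63) - 1)) % self.dim, sign

    def _token_vector(self, token: str) -> np.ndarray:
        """Summed signed feature contributions of one token (cached)."""
        vec = np.zeros(self.dim, dtype=np.float64)
        i, s = self._hash_feature("w:" + token)
        vec[i] += s
        padded = "<" + token + ">"
        for k in range(len(padded) - 2):
            i, s = self._hash_feature("c:" + padded[k : k + 3])
            vec[i] += s
        self._token_cache[token] = vec
        return vec

    # -- encoding ----------------------------------------------------------

    def encode_token_lists(self, token_lists: Sequence[Sequence[str]]) -> np.ndarray:
        """Encode pre-tokenized sentences; fast path shared with ``encode``."""
        n = len(token_lists)
        out = np.zeros((n, self.dim), dtype=np.float64)
        cache = self._token_cache
        for r, tokens in enumerate(token_lists):
            row = out[r]
            for tok in tokens:
                vec = cache.get(tok)
                if vec is None:
                    vec = self._token_vector(tok)
                row += vec
        norms = np.linalg.norm(out, axis=1)
        empty = norms == 0.0
        if np.any(empty):
            out[empty] = 0.0
            out[empty, 0] = 1.0
            norms[empty] = 1.0
        out /= norms[:, None]
        return out

    def encode(self, sentences: Sequence[str]) -> np.ndarray:
        return self.encode_token_lists([self.tokenize(s) for s in sentences])


def builtin_encode(sentence: str, dim: int = 512, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Encode one sentence with the built-in hashing encoder."""
    return HashingEncoder(dim=dim, seed=seed).encode([sentence])[0]


class PretrainedSentenceEncoder:
    """Adapter for a pretrained TensorFlow-Hub universal sentence encoder.

    Loads lazily from a local module path or hub URL; outputs are re-normalised
    to unit L2 norm so inner products remain cosines.  Requires
    ``tensorflow_hub`` to be installed; nothing is downloaded unless the
    caller explicitly passes a remote handle.
    """

    def __init__(self, handle: str, dim: int = 512, encoder_id: str = "guse") -> None:
        try:
            import tensorflow_hub  # type: ignore[import-not-found]
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "PretrainedSentenceEncoder requires the optional 'tensorflow_hub' "
                "package; install it and provide a local module path or hub URL"
            ) from exc
        self._model = tensorflow_hub.load(handle)  # pragma: no cover
        self.dim = int(dim)  # pragma: no cover
        self.encoder_id = encoder_id  # pragma: no cover

    def encode(self, sentences: Sequence[str]) -> np.ndarray:  # pragma: no cover
        raw = np.asarray(self._model(list(sentences)), dtype=np.float64)
        if raw.ndim != 2 or raw.shape[1] != self.dim:
            raise ValueError(f"pretrained encoder returned shape {raw.shape}, expected (n, {self.dim})")
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("pretrained encoder returned a zero vector")
        return raw / norms


_REGISTRY: dict[str, Callable[..., Encoder]] = {}


def _check_contract(encoder: Encoder) -> None:
    probe = encoder.encode(["contract probe one", "probe two"])
    probe = np.asarray(probe, dtype=float)
    if probe.shape != (2, encoder.dim):
        raise ValueError(
            f"encoder {encoder.encoder_id!r} violates contract: shape {probe.shape}"
        )
    if not np.allclose(np.linalg.norm(probe, axis=1), 1.0, atol=_NORM_TOL):
        raise ValueError(f"encoder {encoder.encoder_id!r} violates unit-norm contract")


def register_encoder(name: str, factory: Callable[..., Encoder], *, check: bool = True) -> None:
    """Register an encoder factory under ``name``; contract-checked by default."""
    if check:
        _check_contract(factory())
    _REGISTRY[name] = factory


def get_encoder(name: str, **kwargs) -> Encoder:
    if name not in _REGISTRY:
        raise KeyError(f"unknown encoder {name!r}; available: {sorted(_REGISTRY)}")
    return _REGISTRY[name](**kwargs)


def available_encoders() -> list[str]:
    return sorted(_REGISTRY)


register_encoder("hashing", HashingEncoder, check=False)


def embed_sentences(sentences: SentenceList | Sequence[str], encoder: Encoder) -> EmbeddingSet:
    """Embed the ordered sentences of one post.

    Raises ``ValueError`` on an empty sentence list (filtration guarantees
    at least two sentences per surviving post).
    """
    sents = list(sentences)
    if not sents:
        raise ValueError("cannot embed an empty sentence list")
    vectors = np.asarray(encoder.encode(sents), dtype=float)
    return EmbeddingSet(vectors=vectors, dim=encoder.dim, encoder_id=encoder.encoder_id)
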