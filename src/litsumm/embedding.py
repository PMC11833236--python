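"""Sentence embedding backends.

The production-grade backend wraps a pretrained sentence-transformer (384-d
MiniLM); the default backend is a deterministic hashed n-gram embedder that
needs no model download and is reproducible bit-for-bit, which is what the
topic-clustering stage needs for testable, seedable behaviour.  Both emit
the configured number of columns (default 384).
"""

from __future__ import annotations

import hashlib
from typing import Protocol, Sequence

import numpy as np


class EmbeddingBackend(Protocol):
    dim: int

    def encode(self, texts: Sequence[str]) -> np.ndarray: ...


class HashedNgramEmbedder:
    """Signed feature hashing of word uni/bigrams into a fixed-width vector.

    Each feature (lowercased word unigram or bigram) is hashed with a salt
    derived from ``seed``; one stable hash picks the bucket, a second bit
    picks the sign.  Vectors are L2-normalised, so cosine geometry reflects
    vocabulary overlap — sentences drawn from distinct controlled
    vocabularies land in separable cones.
    """

    def __init__(self, dim: int = 384, seed: int = 0) -> None:
        if dim <= 0:
            raise ValueError("dim must be positive")
        self.dim = dim
        self.seed = seed
        self._salt = f"hne-{seed}-".encode()

    def _features(self, text: str) -> list[str]:
        words = [w.strip(".,;:!?()[]\"'").lower() for w in text.split()]
        words = [w for w in words if w]
        return words + [f"{a}_{b}" for a, b in zip(words, words[1:])]

    def _vector(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim, dtype=np.float64)
        for feat in self._features(text):
            h = hashlib.blake2b(self._salt + feat.encode(), digest_size=8).digest()
            idx = int.from_bytes(h[:4], "little") % self.dim
            sign = 1.0 if h[4] & 1 else -1.0
            v[idx] += sign
        norm = np.linalg.norm(v)
        if norm > 0:
            v /= norm
        return v

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        if len(texts) == 0:
            raise ValueError("cannot embed an empty list of texts")
        return np.vstack([self._vector(t) for t in texts])


class SentenceTransformerEmbedder:
    """Pretrained transformer backend (requires ``sentence-transformers``)."""

    def __init__(self, model_name: str = "all-MiniLM-L6-v2", dim: int = 384) -> None:
        from sentence_transformers import SentenceTransformer  # deferred: optional

        self._model = SentenceTransformer(model_name)
        self.dim = dim

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        if len(texts) == 0:
            raise ValueError("cannot embed an empty list of texts")
        return np.asarray(self._model.encode(list(texts)))


def get_embedder(name: str = "hashed", dim: int = 384, seed: int = 0) -> EmbeddingBackend:
    if name == "hashed":
        return HashedNgramEmbedder(dim=dim, seed=seed)
    if name == "sentence-transformer":
        return SentenceTransformerEmbedder(dim=dim)
    raise ValueError(f"unknown embedding backend {name!r}")
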