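"""Deterministic phrase embeddings for dictionary term linking.

Unseen token variants are linked to dictionary terms by cosine similarity
between phrase embeddings. The default provider hashes character trigrams
into a fixed-dimension count vector and L2-normalizes it: morphological
variants of a term ("angiokeratomata" vs "angiokeratoma") share most of
their trigrams and score high, unrelated words score near zero. The
provider is a plain duck-typed interface (``embed(phrase) -> unit vector``,
``dim``), so pretrained word vectors can be substituted without touching
the matcher.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

__all__ = [
    "EmbeddingProvider",
    "HashedTrigramEmbedder",
    "cosine_similarity",
]


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Anything that maps a phrase to a unit-norm vector of fixed dimension."""

    dim: int

    def embed(self, phrase: str) -> np.ndarray: ...


def _normalize_phrase(phrase: str) -> str:
    return " ".join(phrase.lower().split())


def trigram_bucket(gram: str, dim: int) -> int:
    """Stable hash bucket of a character trigram (independent of PYTHONHASHSEED)."""
    digest = hashlib.blake2b(gram.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") % dim


def char_trigrams(phrase: str) -> list[str]:
    """Character trigrams of the whitespace-normalized phrase.

    Phrases shorter than three characters contribute themselves as a single
    gram so that no non-empty phrase embeds to the zero vector.
    """
    s = _normalize_phrase(phrase)
    if len(s) < 3:
        return [s]
    return [s[i : i + 3] for i in range(len(s) - 2)]


class HashedTrigramEmbedder:
    """Hashed character-trigram embedding, L2-normalized.

    Parameters
    ----------
    dim:
        Vector dimension (number of hash buckets). Default 256.
    """

    def __init__(self, dim: int = 256):
        if dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        self.dim = int(dim)

    def embed(self, phrase: str) -> np.ndarray:
        if not phrase or not phrase.strip():
            raise ValueError("cannot embed an empty phrase")
        vec = np.zeros(self.dim, dtype=np.float64)
        for gram in char_trigrams(phrase):
            vec[trigram_bucket(gram, self.dim)] += 1.0
        vec /= np.linalg.norm(vec)
        return vec

    def buckets(self, phrase: str) -> set[int]:
        """Hash buckets occupied by the phrase's trigrams (for auditing)."""
        return {trigram_bucket(g, self.dim) for g in char_trigrams(phrase)}


def cosine_similarity(u: Iterable[float], v: Iterable[float]) -> float:
    """u.v / (|u||v|), clipped to [-1, 1]. Raises on a zero vector."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
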