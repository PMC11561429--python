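"""Deterministic text encoders fulfilling the TextEncoder/DocumentEncoder contracts.

The contract every consumer in the package relies on: ``encode(text)`` maps a
string to a fixed-dimension finite real vector, deterministically.  The
shipped implementation is a seeded signed hashing bag-of-tokens projector —
each token hashes (keyed blake2b, so stable across processes and immune to
``PYTHONHASHSEED``) to one coordinate and a sign, the signed counts are summed
and L2-normalized.  Texts sharing vocabulary land near each other in cosine
space, which is all the rule-engine-adjacent stages need; a pretrained
contextual encoder can be substituted anywhere the contract is accepted.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache

import numpy as np

from .text import tokenize

SEP_TOKEN = "septoken"
MAX_DOCUMENT_TOKENS = 512


class HashingTextEncoder:
    """Seeded signed-hashing bag-of-tokens encoder (L2-normalized)."""

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = int(dim)
        self.seed = int(seed)
        self._salt = str(seed).encode()

    @lru_cache(maxsize=65536)
    def _token_hash(self, token: str) -> tuple[int, float]:
        digest = hashlib.blake2b(token.encode(), digest_size=8, key=self._salt).digest()
        value = int.from_bytes(digest, "big")
        return value % self.dim, 1.0 if (value >> 32) & 1 else -1.0

    def encode_tokens(self, tokens: list[str]) -> np.ndarray:
        vec = np.zeros(self.dim)
        for token in tokens:
            idx, sign = self._token_hash(token)
            vec[idx] += sign
        norm = float(np.linalg.norm(vec))
        if norm > 0:
            vec /= norm
        return vec

    def encode(self, text: str) -> np.ndarray:
        return self.encode_tokens(tokenize(text))


class HashingDocumentEncoder(HashingTextEncoder):
    """Article-level encoder: title + separator + body, capped at 512 tokens.

    The cap truncates the body tail first (the title always survives), mirroring
    the fixed input window of transformer backbones.
    """

    def __init__(self, dim: int = 64, seed: int = 0, max_tokens: int = MAX_DOCUMENT_TOKENS):
        super().__init__(dim=dim, seed=seed)
        self.max_tokens = int(max_tokens)

    def document_tokens(self, title: str, body: str) -> list[str]:
        tokens = tokenize(title) + [SEP_TOKEN] + tokenize(body)
        return tokens[: self.max_tokens]

    def encode_document(self, title: str, body: str) -> np.ndarray:
        return self.encode_tokens(self.document_tokens(title, body))

    def encode_article(self, article) -> np.ndarray:
        return self.encode_document(article.title, article.body)


class HashingSentenceEncoder(HashingTextEncoder):
    """Per-sentence encoder for the extractive summarizer."""

    def encode_sentences(self, sentences: list[str]) -> np.ndarray:
        if not sentences:
            return np.zeros((0, self.dim))
        return np.stack([self.encode(s) for s in sentences])
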