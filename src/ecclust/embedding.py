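"""Criterion embedding: a uniform contract over pluggable sentence encoders.

Two pooling modes are supported over per-token vectors: ``cls`` (the vector at
the first position) and ``mean_non_pad`` (arithmetic mean over unmasked
positions).  Transformer presets (BERT, Sentence-BERT, PubMed-BERT,
PubMed-Sentence-BERT) can be plugged in through the same protocol when the
relevant libraries and weights are available; all tests and desk-scale runs
use the deterministic hash embedder, which maps each word to a stable
pseudo-random unit vector and needs no model weights.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "TokenEncoder",
    "HashTokenEncoder",
    "embed_texts",
    "fallback_hash_embedder",
    "get_encoder",
    "save_embeddings",
    "load_embeddings",
    "ENCODER_PRESETS",
]

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[0-9a-zA-Z]+")

#: Named presets mirroring the four transformer encoders commonly compared for
#: biomedical sentence embedding; loading real weights requires the optional
#: `transformers` dependency and is never needed by the test suite.
ENCODER_PRESETS = {
    "bert": ("bert-base-uncased", "cls"),
    "sentence-bert": ("sentence-transformers/all-MiniLM-L6-v2", "mean_non_pad"),
    "pubmed-bert": ("microsoft/BiomedNLP-PubMedBERT-base-uncased-abstract", "cls"),
    "pubmed-sentence-bert": ("pritamdeka/S-PubMedBert-MS-MARCO", "mean_non_pad"),
}


class TokenEncoder(Protocol):
    """Anything producing per-token vectors and a padding mask for a text."""

    max_length: int

    def token_vectors(self, text: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(vectors, mask)``: vectors of shape (T, D) and a boolean
        mask of shape (T,), True for real (non-padding) tokens."""
        ...


def _words(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


def _hash_unit_vector(word: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(f"{seed}:{word}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    v = rng.normal(size=dim)
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


@dataclasses.dataclass
class HashTokenEncoder:
    """Deterministic token encoder: each word hashes to a stable unit vector.

    Serves both as the desk-scale stand-in for transformer encoders in
    :func:`embed_texts` and as the token-level embedder for greedy-matching
    text similarity scores.
    """

    dim: int = 128
    seed: int = 0
    max_length: int = 256

    def token_vectors(self, text: str) -> tuple[np.ndarray, np.ndarray]:
        words = _words(text)[: self.max_length]
        if not words:
            return np.zeros((1, self.dim)), np.zeros(1, dtype=bool)
        vecs = np.stack([_hash_unit_vector(w, self.dim, self.seed) for w in words])
        return vecs, np.ones(len(words), dtype=bool)


def embed_texts(
    texts: Sequence[str],
    encoder: TokenEncoder,
    pooling: str = "mean_non_pad",
    batch_size: int = 64,
) -> np.ndarray:
    """Embed texts with the given encoder and pooling mode.

    ``pooling="cls"`` takes the first-position token vector; ``"mean_non_pad"``
    averages over unmasked tokens (falling back to the first position when the
    mask is empty).  Batching is purely an iteration detail and cannot change
    the result.  Encoder failures are re-raised with the offending text index.
    """
    if pooling not in ("cls", "mean_non_pad"):
        raise ValueError(f"unknown pooling mode: {pooling!r}")
    rows: list[np.ndarray] = []
    for start in range(0, len(texts), batch_size):
        for offset, text in enumerate(texts[start : start + batch_size]):
            try:
                vectors, mask = encoder.token_vectors(text)
            except Exception as exc:
                raise RuntimeError(
                    f"encoder failed on text index {start + offset}: {exc}"
                ) from exc
            if pooling == "cls" or not mask.any():
                rows.append(np.asarray(vectors[0], dtype=float))
            else:
                rows.append(np.asarray(vectors[mask].mean(axis=0), dtype=float))
    if not rows:
        return np.zeros((0, 0))
    out = np.stack(rows)
    if not np.isfinite(out).all():
        raise ValueError("embedding matrix contains NaN or Inf")
    return out


def fallback_hash_embedder(
    texts: Sequence[str], dim: int = 128, seed: int = 0
) -> np.ndarray:
    """Bag-of-words hash embedding: L2-normalized sum of stable word vectors.

    Identical texts map to identical rows; word order is irrelevant; texts
    with disjoint vocabularies are near-orthogonal in high dimension.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rows = []
    for text in texts:
        words = _words(text)
        if not words:
            rows.append(np.zeros(dim))
            continue
        v = np.sum([_hash_unit_vector(w, dim, seed) for w in words], axis=0)
        n = np.linalg.norm(v)
        rows.append(v / n if n > 0 else v)
    return np.stack(rows) if rows else np.zeros((0, dim))


def get_encoder(name: str, dim: int = 128, seed: int = 0) -> TokenEncoder:
    """Resolve an encoder handle by name.

    ``"hash"`` returns the deterministic :class:`HashTokenEncoder`.  The
    transformer presets require the optional `transformers` dependency; when
    it is missing an informative ImportError is raised.
    """
    if name == "hash":
        return HashTokenEncoder(dim=dim, seed=seed)
    if name in ENCODER_PRESETS:
        model_name, _ = ENCODER_PRESETS[name]
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                f"encoder preset {name!r} needs the optional 'transformers' "
                f"dependency (model {model_name}); use encoder 'hash' for a "
                "deterministic dependency-free embedder"
            ) from exc
        raise NotImplementedError(
            f"transformer preset {name!r}: plug a TokenEncoder wrapping "
            f"{model_name} into embed_texts()"
        )
    raise KeyError(f"unknown encoder {name!r}; options: hash, {', '.join(ENCODER_PRESETS)}")


def save_embeddings(
    path_prefix: str | Path,
    matrix: np.ndarray,
    criterion_ids: Sequence[str],
    model: str,
    pooling: str,
) -> None:
    """Persist a matrix (.npy) with a JSON sidecar describing its provenance."""
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), matrix)
    sidecar = {
        "criterion_ids": list(criterion_ids),
        "model": model,
        "pooling": pooling,
        "dim": int(matrix.shape[1]) if matrix.ndim == 2 else 0,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")


def load_embeddings(path_prefix: str | Path) -> tuple[np.ndarray, dict]:
    prefix = Path(path_prefix)
    matrix = np.load(prefix.with_suffix(".npy"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text(encoding="utf-8"))
    if len(sidecar["criterion_ids"]) != matrix.shape[0]:
        raise ValueError("embedding sidecar does not match matrix row count")
    return matrix, sidecar
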