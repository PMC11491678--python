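"""Sequence representations for variant-effect regression.

Four schemes, matching the four regressors:

* ``indicator`` — length-L 0/1 vector marking *which* positions are mutated,
  blind to residue identity; two variants with the same mutated positions are
  indistinguishable.
* ``one_hot`` — L×20 block one-hot of the full sequence.
* ``augmented_potts`` — the one-hot vector concatenated with the sequence's
  Potts energy as one extra feature (L×20 + 1).
* ``embedding`` — any user-supplied map from sequence to a fixed-length
  vector; built-in defaults are a seeded random projection of the one-hot
  encoding and an amino-acid composition embedding (no pretrained weights
  are bundled).

Each scheme is exposed both as a plain function and as a scikit-learn
transformer over iterables of sequence strings, so the regressors compose as
ordinary pipelines.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import AA20, AA20_INDEX
from .potts import PottsModel

__all__ = [
    "indicator_encode",
    "one_hot_encode",
    "one_hot_decode",
    "augment_encoding",
    "IndicatorEncoder",
    "OneHotEncoder",
    "AugmentedPottsEncoder",
    "EmbeddingEncoder",
    "random_projection_embedder",
    "aa_composition_embedder",
]

Embedder = Callable[[str], np.ndarray]


def indicator_encode(sequence: str, reference: str) -> np.ndarray:
    """Length-L 0/1 vector; entry i is 1 iff the variant differs at position i+1."""
    if len(sequence) != len(reference):
        raise ValueError("sequence/reference length mismatch")
    return np.fromiter(
        (1.0 if a != b else 0.0 for a, b in zip(sequence, reference)),
        dtype=float,
        count=len(reference),
    )


def one_hot_encode(sequence: str) -> np.ndarray:
    """L×20 binary vector, one hot block per position."""
    L = len(sequence)
    out = np.zeros(L * 20)
    for i, aa in enumerate(sequence):
        k = AA20_INDEX.get(aa)
        if k is None:
            raise ValueError(f"non-canonical residue {aa!r} at position {i + 1}")
        out[i * 20 + k] = 1.0
    return out


def one_hot_decode(vector: np.ndarray) -> str:
    blocks = np.asarray(vector).reshape(-1, 20)
    if not np.allclose(blocks.sum(axis=1), 1.0):
        raise ValueError("not a valid one-hot encoding")
    return "".join(AA20[k] for k in blocks.argmax(axis=1))


def augment_encoding(sequence: str, reference: str, potts: PottsModel) -> np.ndarray:
    """One-hot encoding concatenated with the Potts sequence energy (L×20+1)."""
    if len(sequence) != len(reference):
        raise ValueError("sequence/reference length mismatch")
    return np.concatenate([one_hot_encode(sequence), [potts.energy(sequence)]])


class _SequenceTransformer(TransformerMixin, BaseEstimator):
    """Base class: stateless transform over an iterable of sequence strings."""

    def fit(self, X: Iterable[str], y=None):
        self._validate(list(X))
        return self

    def _validate(self, seqs: Sequence[str]) -> None:
        pass

    def transform(self, X: Iterable[str]) -> np.ndarray:
        seqs = list(X)
        if not seqs:
            return np.empty((0, self.dimensionality()))
        return np.stack([self._encode_one(s) for s in seqs])

    def _encode_one(self, seq: str) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def dimensionality(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError


class IndicatorEncoder(_SequenceTransformer):
    """Residue-agnostic indicator encoding relative to a reference sequence."""

    def __init__(self, reference: str):
        self.reference = reference

    def _encode_one(self, seq: str) -> np.ndarray:
        return indicator_encode(seq, self.reference)

    def dimensionality(self) -> int:
        return len(self.reference)


class OneHotEncoder(_SequenceTransformer):
    def __init__(self, reference: str):
        self.reference = reference

    def _encode_one(self, seq: str) -> np.ndarray:
        if len(seq) != len(self.reference):
            raise ValueError("sequence/reference length mismatch")
        return one_hot_encode(seq)

    def dimensionality(self) -> int:
        return 20 * len(self.reference)


class AugmentedPottsEncoder(_SequenceTransformer):
    """One-hot plus Potts energy; the energy feature is the last column."""

    def __init__(self, reference: str, potts: PottsModel):
        self.reference = reference
        self.potts = potts

    def transform(self, X: Iterable[str]) -> np.ndarray:
        seqs = list(X)
        if not seqs:
            return np.empty((0, self.dimensionality()))
        onehot = np.stack([one_hot_encode(s) for s in seqs])
        energies = self.potts.energies(seqs)
        return np.hstack([onehot, energies[:, None]])

    def dimensionality(self) -> int:
        return 20 * len(self.reference) + 1


class EmbeddingEncoder(_SequenceTransformer):
    """Wrap any sequence-level embedder (sequence -> fixed-length vector)."""

    def __init__(self, embedder: Embedder):
        self.embedder = embedder

    def _encode_one(self, seq: str) -> np.ndarray:
        v = np.asarray(self.embedder(seq), dtype=float).ravel()
        if not np.isfinite(v).all():
            raise ValueError("embedder produced non-finite values")
        return v

    def dimensionality(self) -> int:
        raise AttributeError("embedding dimensionality is embedder-defined")


def random_projection_embedder(reference: str, dim: int = 1024, seed: int = 0) -> Embedder:
    """Seeded Gaussian random projection of the one-hot encoding.

    A linear, download-free default: ridge on these features approximates
    ridge on the full one-hot encoding while keeping the embedding
    sequence-level and fixed-length.
    """
    rng = np.random.default_rng(seed)
    P = rng.standard_normal((20 * len(reference), dim)) / np.sqrt(dim)

    def embed(seq: str) -> np.ndarray:
        return one_hot_encode(seq) @ P

    return embed


def aa_composition_embedder(seq: str) -> np.ndarray:
    """20-dim amino-acid composition (position-free global features)."""
    counts = np.zeros(20)
    for aa in seq:
        k = AA20_INDEX.get(aa)
        if k is None:
            raise ValueError(f"non-canonical residue {aa!r}")
        counts[k] += 1
    return counts / max(len(seq), 1)
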