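"""Potts (pairwise Markov random field) sequence model over an MSA.

The model assigns every aligned sequence sigma an energy

    E(sigma) = sum_i h_i(sigma_i) + sum_{i<j} J_ij(sigma_i, sigma_j)

with per-site fields h over a 21-state alphabet (20 amino acids + gap) and
pairwise couplings J. Fitting maximizes the L2-regularized site
pseudolikelihood — the sum over sites of the conditional log-likelihood of
each column given the rest of the sequence — by gradient ascent from a zero
initialization, which is the standard tractable surrogate for the intractable
full likelihood in the direct-coupling literature.

Internally couplings are kept as one symmetric (L*q, L*q) matrix W with zero
diagonal blocks, so W[(i,a),(j,b)] = J_ij(a,b); the conditional logits for
all sites of all sequences are then a single matrix product with the one-hot
encoded alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AA21, AA21_INDEX, GAP

__all__ = [
    "MSA",
    "PottsModel",
    "potts_energy",
    "fit_potts",
    "pseudolikelihood",
    "save_potts",
    "load_potts",
]


class MSA:
    """An aligned set of sequences over the 21-state alphabet.

    Rows must have equal length. For A2M input, lowercase letters and ``.``
    denote insert states and are dropped; uppercase letters and ``-`` are
    match columns. Characters outside the alphabet (e.g. ``X``) are mapped to
    the gap state with a warning.
    """

    def __init__(self, sequences: Sequence[str], ids: Sequence[str] | None = None):
        rows = [s.upper() for s in (seq.replace(".", "").translate(_DEL_LOWER) for seq in sequences)]
        if not rows:
            raise ValueError("empty MSA")
        L = len(rows[0])
        if any(len(r) != L for r in rows):
            raise ValueError("MSA rows have unequal lengths")
        mat = np.empty((len(rows), L), dtype=np.int8)
        n_unknown = 0
        for i, row in enumerate(rows):
            for j, ch in enumerate(row):
                idx = AA21_INDEX.get(ch)
                if idx is None:
                    idx = AA21_INDEX[GAP]
                    n_unknown += 1
                mat[i, j] = idx
        if n_unknown:
            warnings.warn(f"{n_unknown} non-canonical characters mapped to the gap state")
        self.matrix = mat
        self.ids = list(ids) if ids is not None else [f"seq{i}" for i in range(len(rows))]

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def gap_ratio(self) -> np.ndarray:
        return (self.matrix == AA21_INDEX[GAP]).mean(axis=0)

    def sequences(self) -> list[str]:
        return ["".join(AA21[a] for a in row) for row in self.matrix]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MSA":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no sequences")
        return cls([str(r.seq) for r in records], ids=[r.id for r in records])


_DEL_LOWER = {ord(c): None for c in "abcdefghijklmnopqrstuvwxyz"}


@dataclass
class PottsModel:
    h: np.ndarray  # (L, q) fields
    W: np.ndarray  # (L*q, L*q) symmetric couplings, zero diagonal blocks
    alphabet: str = AA21
    columns: np.ndarray | None = None  # original 0-based column indices kept at fit time
    converged: bool = True

    def __post_init__(self) -> None:
        L, q = self.h.shape
        if self.W.shape != (L * q, L * q):
            raise ValueError("W shape inconsistent with h")
        if not np.isfinite(self.h).all() or not np.isfinite(self.W).all():
            raise ValueError("non-finite Potts parameters")
        if self.columns is None:
            self.columns = np.arange(L)

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def coupling(self, i: int, j: int) -> np.ndarray:
        """J_ij as a (q, q) block, defined for i < j."""
        if not 0 <= i < j < self.L:
            raise ValueError("couplings are defined for 0 <= i < j < L")
        q = self.q
        return self.W[i * q : (i + 1) * q, j * q : (j + 1) * q]

    def coupling_norms(self) -> np.ndarray:
        """(L, L) matrix of Frobenius norms of J_ij (upper triangle, i<j)."""
        q, L = self.q, self.L
        blocks = self.W.reshape(L, q, L, q)
        norms = np.sqrt((blocks**2).sum(axis=(1, 3)))
        return np.triu(norms, k=1)

    def _encode(self, sequence: str) -> np.ndarray:
        idx = np.empty(self.L, dtype=np.int64)
        seq = sequence
        if len(seq) != self.L:
            if self.columns is not None and len(seq) >= int(self.columns.max()) + 1:
                seq = "".join(seq[c] for c in self.columns)
            else:
                raise ValueError(f"sequence length {len(sequence)} incompatible with model L={self.L}")
        lookup = {aa: k for k, aa in enumerate(self.alphabet)}
        for i, ch in enumerate(seq):
            if ch not in lookup:
                raise ValueError(f"character {ch!r} outside model alphabet")
            idx[i] = lookup[ch]
        return idx

    def energy(self, sequence: str) -> float:
        return float(self.energies([sequence])[0])

    def energies(self, sequences: Sequence[str]) -> np.ndarray:
        """Vectorized E(sigma) for a batch of sequences."""
        idx = np.stack([self._encode(s) for s in sequences])
        X = _one_hot(idx, self.q)
        field_term = np.take_along_axis(self.h[None, :, :], idx[:, :, None], axis=2)[:, :, 0].sum(axis=1)
        pair_term = 0.5 * np.einsum("nk,nk->n", X @ self.W, X)
        return field_term + pair_term


def potts_energy(model: PottsModel, sequence: str) -> float:
    """Sequence energy: field sum plus coupling sum over all pairs i < j."""
    return model.energy(sequence)


def _one_hot(idx: np.ndarray, q: int) -> np.ndarray:
    N, L = idx.shape
    X = np.zeros((N, L * q))
    X[np.arange(N)[:, None], np.arange(L)[None, :] * q + idx] = 1.0
    return X


def pseudolikelihood(
    h: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    l2_field: float,
    l2_coupling: float,
    weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Regularized pseudolikelihood and its analytic gradient.

    ``X`` is the one-hot encoded alignment, shape (N, L*q). Returns
    ``(objective, grad_h, grad_W)`` where the objective is

        mean_n sum_i log P(x_ni | x_n,-i) - l2_field*||h||^2
        - (l2_coupling/2)*||W_offdiag||^2

    (a weighted mean over sequences, so the regularization strengths are
    independent of alignment depth; the coupling penalty halves the
    off-diagonal sum so it equals l2_coupling * sum_{i<j} ||J_ij||_F^2).
    The gradient is the projection onto symmetric W with zero diagonal
    blocks, i.e. the exact gradient in the tied parametrization where
    W[(i,a),(j,b)] and W[(j,b),(i,a)] are one parameter.
    """
    L, q = h.shape
    N = X.shape[0]
    w = np.ones(N) if weights is None else np.asarray(weights, dtype=float)
    wsum = float(w.sum())

    logits = (X @ W + h.reshape(1, -1)).reshape(N, L, q)
    m = logits.max(axis=2, keepdims=True)
    lse = (m[:, :, 0] + np.log(np.exp(logits - m).sum(axis=2)))  # (N, L)
    Xr = X.reshape(N, L, q)
    ll_site = (Xr * logits).sum(axis=2) - lse  # (N, L)
    pll = float(w @ ll_site.sum(axis=1)) / wsum

    P = np.exp(logits - lse[:, :, None])  # softmax, (N, L, q)
    D = ((Xr - P) * w[:, None, None]).reshape(N, L * q) / wsum
    grad_h = D.sum(axis=0).reshape(L, q) - 2.0 * l2_field * h
    G = D.T @ X
    G = 0.5 * (G + G.T)
    _zero_diag_blocks(G, L, q)
    Wpen = W.copy()
    _zero_diag_blocks(Wpen, L, q)  # W already has zero diagonal blocks, but be safe
    grad_W = G - l2_coupling * Wpen
    obj = pll - l2_field * float((h**2).sum()) - 0.5 * l2_coupling * float((Wpen**2).sum())
    return obj, grad_h, grad_W


def _zero_diag_blocks(M: np.ndarray, L: int, q: int) -> None:
    for i in range(L):
        M[i * q : (i + 1) * q, i * q : (i + 1) * q] = 0.0


def _identity_weights(matrix: np.ndarray, threshold: float) -> np.ndarray:
    """1 / (number of neighbors at >= threshold identity), the DCA convention."""
    N = matrix.shape[0]
    sim = np.zeros((N, N), dtype=bool)
    L = matrix.shape[1]
    for i in range(N):
        sim[i] = (matrix == matrix[i]).mean(axis=1) >= threshold
    return 1.0 / sim.sum(axis=1)


def fit_potts(
    msa: MSA,
    l2_field: float = 0.01,
    l2_coupling: float | None = None,
    gap_cutoff: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-4,
    reweight_identity: float | None = None,
) -> PottsModel:
    """Fit fields and couplings by regularized pseudolikelihood ascent.

    Parameters
    ----------
    l2_coupling
        Defaults to ``0.1 * (L - 1)``, scaling the coupling penalty with the
        number of pairs each site participates in.
    gap_cutoff
        Columns whose gap ratio strictly exceeds this are dropped before
        fitting. The default of 1 keeps every column, so parameters exist for
        every residue of the query.
    reweight_identity
        If given (e.g. 0.8), sequences are down-weighted by the number of
        alignment neighbors at that identity level; off by default.

    The optimizer is deterministic: zero initialization, monotone gradient
    ascent with a backtracking step size, stopping when the largest parameter
    change drops below ``tol``. On hitting ``max_iter`` a warning is issued
    and the partial model is returned with ``converged=False``.
    """
    if msa.n_sequences < 2:
        raise ValueError("need at least 2 sequences to fit a Potts model")
    keep = np.flatnonzero(msa.gap_ratio() <= gap_cutoff)
    if keep.size == 0:
        raise ValueError("gap_cutoff removed every column")
    mat = msa.matrix[:, keep].astype(np.int64)
    N, L = mat.shape
    q = len(AA21)
    if l2_coupling is None:
        l2_coupling = 0.1 * max(L - 1, 1)
    weights = None
    if reweight_identity is not None:
        weights = _identity_weights(mat, reweight_identity)

    X = _one_hot(mat, q)
    h = np.zeros((L, q))
    W = np.zeros((L * q, L * q))
    lr = 1.0
    obj, gh, gW = pseudolikelihood(h, W, X, l2_field, l2_coupling, weights)
    converged = False
    for _it in range(max_iter):
        h_new = h + lr * gh
        W_new = W + lr * gW
        obj_new, gh_new, gW_new = pseudolikelihood(h_new, W_new, X, l2_field, l2_coupling, weights)
        if obj_new < obj:
            lr *= 0.5  # overshoot: shrink and retry from the same point
            if lr < 1e-12:
                converged = True
                break
            continue
        delta = max(float(np.abs(h_new - h).max()), float(np.abs(W_new - W).max()))
        h, W, obj, gh, gW = h_new, W_new, obj_new, gh_new, gW_new
        lr *= 1.1
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"Potts fit did not converge within {max_iter} iterations (tol={tol})")
    return PottsModel(h=h, W=W, alphabet=AA21, columns=keep, converged=converged)


def save_potts(model: PottsModel, path: str | Path) -> None:
    """Serialize to an .npz container (fields, couplings, alphabet, columns)."""
    np.savez_compressed(
        path,
        h=model.h,
        W=model.W,
        alphabet=np.array(list(model.alphabet)),
        columns=model.columns,
        converged=np.array(model.converged),
    )


def load_potts(path: str | Path) -> PottsModel:
    data = np.load(path, allow_pickle=False)
    return PottsModel(
        h=data["h"],
        W=data["W"],
        alphabet="".join(data["alphabet"]),
        columns=data["columns"],
        converged=bool(data["converged"]),
    )
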