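"""Combinatorial variant library design over factorial position bins.

Equal numbers of variants are sampled from every non-empty bin: the mutation
count per variant is uniform on 1..min(8, bin size), positions are drawn
uniformly without replacement within the bin, and alternative residues come
either from a pluggable per-position scorer (75% of variants by default,
standing in for protein-language-model likelihoods used to bias libraries
toward expressible sequences) or uniformly over the 19 alternatives. By
construction every variant is class-pure: all its mutated positions share all
four binary labels, so no variant is lost when splitting by characteristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, AA20_INDEX, Mutation, apply_mutations, format_mutations
from .partitioning import PositionPartition

__all__ = [
    "VariantSpec",
    "DesignConfig",
    "uniform_scorer",
    "blosum62_scorer",
    "sample_variant",
    "design_library",
    "enumerate_single_variants",
    "count_single_variants",
    "library_to_frame",
    "write_library_fasta",
]

Scorer = Callable[[int], np.ndarray]  # position -> 20 non-negative weights over AA20


@dataclass(frozen=True)
class VariantSpec:
    mutations: frozenset[Mutation]
    bin_signature: tuple[int, ...] | None = None
    mode: str = "uniform"  # "scorer" | "uniform"

    def sequence(self, reference: str) -> str:
        return apply_mutations(reference, self.mutations)

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)


@dataclass
class DesignConfig:
    n_per_bin: int
    max_mutations: int = 8
    scorer_fraction: float = 0.75
    scorer: Scorer | None = None
    seed: int = 0
    max_resample: int = 1000  # duplicate-resampling attempts per variant
    cap_to_capacity: bool = False  # shrink a tiny bin's target instead of erroring
    min_bin_positions: int = 0  # skip bins with fewer positions (0 = keep all)

    def __post_init__(self) -> None:
        if self.n_per_bin <= 0:
            raise ValueError("n_per_bin must be positive")
        if not 0.0 <= self.scorer_fraction <= 1.0:
            raise ValueError("scorer_fraction must be in [0, 1]")
        if self.max_mutations < 1:
            raise ValueError("max_mutations must be >= 1")


def uniform_scorer(_position: int) -> np.ndarray:
    return np.ones(20)


def blosum62_scorer(reference: str, temperature: float = 2.0) -> Scorer:
    """Substitution-matrix scorer: weights ∝ exp(BLOSUM62[wt, a] / T).

    A download-free stand-in for language-model likelihoods: conservative
    substitutions get higher sampling weight than disruptive ones.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")

    def score(position: int) -> np.ndarray:
        wt = reference[position - 1]
        row = np.array([blosum[wt, a] for a in AA20], dtype=float)
        return np.exp(row / temperature)

    return score


def _draw_alt(wt: str, rng: np.random.Generator, scorer: Scorer | None, position: int) -> str:
    if scorer is None:
        alts = [a for a in AA20 if a != wt]
        return alts[rng.integers(len(alts))]
    w = np.asarray(scorer(position), dtype=float).copy()
    if w.shape != (20,) or (w < 0).any():
        raise ValueError("scorer must return 20 non-negative weights")
    w[AA20_INDEX[wt]] = 0.0  # the wild type is never an "alternative"
    total = w.sum()
    if total <= 0:
        raise ValueError(f"scorer left no admissible residue at position {position}")
    return AA20[rng.choice(20, p=w / total)]


def sample_variant(
    bin_positions: Sequence[int],
    reference: str,
    config: DesignConfig,
    rng: np.random.Generator,
    mode: str = "uniform",
    n_mutations: int | None = None,
) -> VariantSpec:
    """Draw one variant from a bin: uniform mutation count, uniform positions.

    ``n_mutations`` fixes the mutation count (used by :func:`design_library`
    to spread counts exactly evenly); by default it is drawn uniformly from
    1..min(max_mutations, bin size).
    """
    positions = sorted(set(bin_positions))
    if not positions:
        raise ValueError("empty bin")
    if max(positions) > len(reference):
        raise ValueError("reference shorter than the largest bin position")
    cap = min(config.max_mutations, len(positions))
    n_mut = int(rng.integers(1, cap + 1)) if n_mutations is None else int(n_mutations)
    if not 1 <= n_mut <= cap:
        raise ValueError(f"n_mutations={n_mut} outside 1..{cap}")
    chosen = rng.choice(positions, size=n_mut, replace=False)
    scorer = config.scorer if mode == "scorer" else None
    muts = frozenset(
        Mutation(int(p), reference[int(p) - 1], _draw_alt(reference[int(p) - 1], rng, scorer, int(p)))
        for p in chosen
    )
    return VariantSpec(mutations=muts, mode=mode)


def _bin_capacity(n_positions: int, max_mutations: int) -> float:
    """Number of distinct variants drawable from a bin (19 alts per site)."""
    from math import comb

    return float(
        sum(comb(n_positions, m) * 19**m for m in range(1, min(max_mutations, n_positions) + 1))
    )


def design_library(
    partition: PositionPartition,
    reference: str,
    config: DesignConfig,
    rng: np.random.Generator | None = None,
) -> list[VariantSpec]:
    """Sample ``n_per_bin`` unique variants from every non-empty bin.

    A bin too small to yield the requested number of unique variants raises,
    unless ``config.cap_to_capacity`` is set, in which case the bin's target
    is shrunk to half its combinatorial capacity with a warning (the screen
    then has unequal bin yields, as real cloning pipelines do).

    ``config.min_bin_positions`` (e.g. ``max_mutations``) skips bins with
    fewer positions: such bins can only host low-order variants, which skews
    the mutation-count mix of every class containing them — the design aims
    for similar mutation-count distributions across classes.
    """
    import warnings

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.scorer_fraction > 0 and config.scorer is None:
        raise ValueError("scorer_fraction > 0 requires a scorer")
    library: list[VariantSpec] = []
    for sig in sorted(partition.bins):
        members = sorted(partition.bins[sig])
        if not members:
            warnings.warn(f"bin {''.join(map(str, sig))} is empty; skipped")
            continue
        if len(members) < config.min_bin_positions:
            warnings.warn(
                f"bin {''.join(map(str, sig))} has {len(members)} position(s) "
                f"< min_bin_positions={config.min_bin_positions}; skipped"
            )
            continue
        n_target = config.n_per_bin
        capacity = _bin_capacity(len(members), config.max_mutations)
        if config.cap_to_capacity and n_target > capacity // 2:
            n_target = max(int(capacity // 2), 1)
            warnings.warn(
                f"bin {''.join(map(str, sig))} holds {len(members)} position(s); "
                f"target capped at {n_target} variants"
            )
        n_scorer = int(round(n_target * config.scorer_fraction))
        modes = ["scorer"] * n_scorer + ["uniform"] * (n_target - n_scorer)
        # spread mutation counts exactly evenly over 1..cap (uniform with the
        # lowest possible variance, keeping the count mix comparable between bins)
        cap = min(config.max_mutations, len(members))
        counts = [(k % cap) + 1 for k in range(n_target)]
        seen: set[frozenset[Mutation]] = set()
        for mode, n_mut in zip(modes, counts):
            for _attempt in range(config.max_resample):
                v = sample_variant(members, reference, config, rng, mode=mode, n_mutations=n_mut)
                if v.mutations not in seen:
                    seen.add(v.mutations)
                    library.append(VariantSpec(v.mutations, bin_signature=sig, mode=mode))
                    break
            else:
                raise RuntimeError(
                    f"bin {''.join(map(str, sig))} too small for {n_target} unique variants"
                )
    return library


def enumerate_single_variants(
    reference: str, exclude_positions: Sequence[int] = ()
) -> Iterator[VariantSpec]:
    """Yield every single-substitution variant (the SSM design space)."""
    excluded = set(exclude_positions)
    for i, wt in enumerate(reference, start=1):
        if i in excluded:
            continue
        for alt in AA20:
            if alt != wt:
                yield VariantSpec(mutations=frozenset({Mutation(i, wt, alt)}))


def count_single_variants(reference: str, exclude_positions: Sequence[int] = ()) -> int:
    """Size of the SSM design space: 19 substitutions per included position."""
    return 19 * (len(reference) - len(set(exclude_positions)))


def library_to_frame(library: Sequence[VariantSpec], reference: str) -> pd.DataFrame:
    rows = []
    for k, v in enumerate(library):
        rows.append(
            {
                "variant_id": f"v{k:05d}",
                "bin_signature": "".join(map(str, v.bin_signature)) if v.bin_signature else "",
                "mode": v.mode,
                "mutations": format_mutations(v.mutations),
                "sequence": v.sequence(reference),
            }
        )
    return pd.DataFrame(rows)


def write_library_fasta(library: Sequence[VariantSpec], reference: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in enumerate(library):
            fh.write(f">v{k:05d} {format_mutations(v.mutations)}\n{v.sequence(reference)}\n")
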