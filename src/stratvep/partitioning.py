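"""Median binarization of structural characteristics and factorial binning.

Each position gets four binary labels (buried, many_contacts,
close_to_active_site, helix_or_sheet) by thresholding the continuous
characteristics at their medians; the 2^4 = 16 label combinations define the
factorial bins from which combinatorial variants are sampled. A variant
belongs to the positive (negative) class of one characteristic iff *all* its
mutated positions carry the positive (negative) label; mixed variants are
excluded from that characteristic's contrast.

Ties at the median go to the negative class: the comparisons are strict
("higher than the median", "closer than the median distance"), so discrete
features such as contact counts can yield unequal class sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure import StructuralProfile

__all__ = [
    "CHARACTERISTICS",
    "BinaryProfile",
    "PositionPartition",
    "binarize_profile",
    "assign_bins",
    "split_variants",
]

#: Fixed signature bit order used everywhere downstream.
CHARACTERISTICS = ("buried", "many_contacts", "close_to_active_site", "helix_or_sheet")


@dataclass
class BinaryProfile:
    labels: pd.DataFrame  # index: position; columns: CHARACTERISTICS, values 0/1
    thresholds: dict[str, float]  # medians used (helix_or_sheet has no threshold)

    def __post_init__(self) -> None:
        missing = set(CHARACTERISTICS) - set(self.labels.columns)
        if missing:
            raise ValueError(f"missing label columns: {missing}")
        vals = self.labels[list(CHARACTERISTICS)].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    @property
    def positions(self) -> np.ndarray:
        return self.labels.index.to_numpy()

    def signature(self, position: int) -> tuple[int, ...]:
        row = self.labels.loc[position, list(CHARACTERISTICS)]
        return tuple(int(v) for v in row)


def binarize_profile(profile: StructuralProfile) -> BinaryProfile:
    """Threshold the continuous characteristics at their medians.

    Positive labels: buriedness strictly above its median; contact count
    strictly above its median; active-site distance strictly *below* its
    median (closeness is the positive trait); secondary structure is already
    binary and passes through.
    """
    t = profile.table
    if len(t) == 0:
        raise ValueError("empty profile")
    med_bur = float(t["buriedness"].median())
    med_con = float(t["n_contacts"].median())
    med_act = float(t["active_site_distance"].median())
    labels = pd.DataFrame(
        {
            "buried": (t["buriedness"] > med_bur).astype(int),
            "many_contacts": (t["n_contacts"] > med_con).astype(int),
            "close_to_active_site": (t["active_site_distance"] < med_act).astype(int),
            "helix_or_sheet": t["ss"].astype(int),
        },
        index=t.index,
    )
    thresholds = {
        "buried": med_bur,
        "many_contacts": med_con,
        "close_to_active_site": med_act,
    }
    return BinaryProfile(labels=labels, thresholds=thresholds)


@dataclass
class PositionPartition:
    """Mapping of positions to the 16 factorial bins."""

    bins: dict[tuple[int, ...], frozenset[int]]
    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        all_pos: set[int] = set()
        for sig, members in self.bins.items():
            if len(sig) != 4 or any(b not in (0, 1) for b in sig):
                raise ValueError(f"bad bin signature {sig}")
            if all_pos & members:
                raise ValueError("bins are not disjoint")
            all_pos |= members

    @property
    def n_positions(self) -> int:
        return sum(len(m) for m in self.bins.values())

    def positive_positions(self, characteristic: str) -> frozenset[int]:
        """Union of the 8 bins with the characteristic's signature bit set."""
        k = CHARACTERISTICS.index(characteristic)
        out: set[int] = set()
        for sig, members in self.bins.items():
            if sig[k] == 1:
                out |= members
        return frozenset(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sig, members in sorted(self.bins.items()):
            for pos in sorted(members):
                rows.append(
                    dict(zip(("position",) + CHARACTERISTICS, (pos,) + sig))
                    | {"bin_signature": "".join(map(str, sig))}
                )
        return pd.DataFrame(rows).set_index("position").sort_index()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().reset_index().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PositionPartition":
        df = pd.read_csv(path, dtype={"bin_signature": str})
        bins: dict[tuple[int, ...], set[int]] = {}
        for _, row in df.iterrows():
            sig = tuple(int(c) for c in row["bin_signature"])
            bins.setdefault(sig, set()).add(int(row["position"]))
        return cls(bins={s: frozenset(m) for s, m in bins.items()}, thresholds={})

    def summary(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "bin_sizes": {"".join(map(str, s)): len(m) for s, m in sorted(self.bins.items())},
            "n_positions": self.n_positions,
            "n_empty_bins": 16 - sum(1 for m in self.bins.values() if m),
        }

    def save_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def assign_bins(binary: BinaryProfile) -> PositionPartition:
    """Place every position in exactly one of the 16 factorial bins."""
    from itertools import product

    bins: dict[tuple[int, ...], set[int]] = {sig: set() for sig in product((0, 1), repeat=4)}
    for pos in binary.positions:
        bins[binary.signature(int(pos))].add(int(pos))
    return PositionPartition(
        bins={s: frozenset(m) for s, m in bins.items()}, thresholds=dict(binary.thresholds)
    )


def _mutated_positions(variant) -> frozenset[int]:
    muts = getattr(variant, "mutations", None)
    if muts is None:
        raise TypeError(f"object {variant!r} has no .mutations")
    return frozenset(m.position for m in muts)


def split_variants(
    variants: Sequence,
    binary: BinaryProfile,
    characteristic: str,
) -> tuple[list, list, list]:
    """Split variants into positive/negative classes for one characteristic.

    Returns ``(positive, negative, excluded)``; a variant is excluded when its
    mutated positions mix labels (or when it has no mutations at all).
    """
    if characteristic not in CHARACTERISTICS:
        raise ValueError(f"unknown characteristic {characteristic!r}")
    col = binary.labels[characteristic]
    known = set(binary.positions.tolist())
    pos_cls, neg_cls, excluded = [], [], []
    for v in variants:
        mpos = _mutated_positions(v)
        if not mpos:
            excluded.append(v)
            continue
        unknown = mpos - known
        if unknown:
            raise ValueError(f"variant has unlabeled position(s) {sorted(unknown)}")
        labs = {int(col.loc[p]) for p in mpos}
        if labs == {1}:
            pos_cls.append(v)
        elif labs == {0}:
            neg_cls.append(v)
        else:
            excluded.append(v)
    return pos_cls, neg_cls, excluded
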