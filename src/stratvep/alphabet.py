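"""Amino-acid alphabets and mutation-string utilities.

The 20 canonical residues are kept in a fixed order that every encoder and
the Potts model share; the 21st state is the alignment gap, used only when
fitting to MSAs (assay variants never contain gaps).
"""

from __future__ import annotations

import re
from typing import Iterable, NamedTuple

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AA21 = AA20 + GAP

AA20_INDEX = {aa: i for i, aa in enumerate(AA20)}
AA21_INDEX = {aa: i for i, aa in enumerate(AA21)}

_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class Mutation(NamedTuple):
    """A single substitution: wild-type residue, 1-based position, alternative."""

    position: int
    wt: str
    alt: str

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.alt}"


def parse_mutation(token: str) -> Mutation:
    """Parse a mutation string like ``"A10V"`` (1-based position)."""
    m = _MUT_RE.match(token.strip())
    if m is None:
        raise ValueError(f"not a valid mutation string: {token!r}")
    wt, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    for aa in (wt, alt):
        if aa not in AA20_INDEX:
            raise ValueError(f"unknown amino acid {aa!r} in {token!r}")
    if wt == alt:
        raise ValueError(f"synonymous mutation {token!r}")
    return Mutation(pos, wt, alt)


def parse_mutations(field: str) -> frozenset[Mutation]:
    """Parse a semicolon-joined mutation field like ``"A10V;K57E"``.

    An empty field denotes the unmutated reference.
    """
    field = field.strip()
    if not field:
        return frozenset()
    muts = [parse_mutation(tok) for tok in field.split(";") if tok.strip()]
    positions = [m.position for m in muts]
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate mutated position in {field!r}")
    return frozenset(muts)


def format_mutations(mutations: Iterable[Mutation]) -> str:
    return ";".join(str(m) for m in sorted(mutations))


def apply_mutations(reference: str, mutations: Iterable[Mutation]) -> str:
    """Return the variant sequence obtained by applying substitutions.

    Raises if a stated wild-type residue disagrees with the reference.
    """
    seq = list(reference)
    for m in mutations:
        if not 1 <= m.position <= len(reference):
            raise ValueError(f"position {m.position} outside reference (L={len(reference)})")
        if seq[m.position - 1] != m.wt:
            raise ValueError(
                f"wild-type mismatch at {m.position}: reference has "
                f"{seq[m.position - 1]}, mutation says {m.wt}"
            )
        seq[m.position - 1] = m.alt
    return "".join(seq)


def mutations_from_pair(reference: str, variant: str) -> frozenset[Mutation]:
    """Diff two equal-length sequences into a mutation set."""
    if len(reference) != len(variant):
        raise ValueError("sequence length mismatch")
    return frozenset(
        Mutation(i + 1, r, v)
        for i, (r, v) in enumerate(zip(reference, variant))
        if r != v
    )
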