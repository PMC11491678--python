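"""Shared fixtures: hand-built structures and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from stratvep.structure import Residue, StructureModel


def chain_structure(
    coords: np.ndarray,
    ss_records: list[tuple[str, int, int]] | None = None,
    aas: str | None = None,
) -> StructureModel:
    """Cα-only structure from an (n, 3) coordinate array, positions 1..n."""
    coords = np.asarray(coords, dtype=float)
    aas = aas or "A" * len(coords)
    residues = [
        Residue(position=i + 1, aa=aas[i], ca=coords[i], atoms=coords[i][None, :].copy())
        for i in range(len(coords))
    ]
    return StructureModel(residues=residues, ss_records=ss_records or [])


@pytest.fixture(scope="session")
def cube_structure() -> StructureModel:
    """Unit-cube corners (8 residues) plus one residue at the center.

    The center atom sits exactly 0.5 from every face of the convex hull.
    """
    corners = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    coords = np.vstack([corners, [[0.5, 0.5, 0.5]]])
    return chain_structure(coords)


@pytest.fixture(scope="session")
def random_cloud() -> StructureModel:
    """50 residues scattered in a 20 Å box (seeded)."""
    rng = np.random.default_rng(42)
    return chain_structure(rng.uniform(0, 20, size=(50, 3)))


@pytest.fixture(scope="session")
def toy_study():
    """One full default synthetic structure + partition, shared across tests."""
    from stratvep.partitioning import assign_bins, binarize_profile
    from stratvep.structure import build_profile
    from stratvep.synthetic import generate_toy_structure

    model, intended = generate_toy_structure(200, seed=0)
    profile = build_profile(model, list(intended.attrs["active_sites"]))
    binary = binarize_profile(profile)
    partition = assign_bins(binary)
    return {
        "model": model,
        "intended": intended,
        "profile": profile,
        "binary": binary,
        "partition": partition,
    }
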