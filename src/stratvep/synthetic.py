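"""Synthetic structures, MSAs and activity screens for end-to-end testing.

The generator emulates the statistical shape of a stratified enzyme
engineering study without any downloads:

* **structures** — a compact globule built by filling an oblate ellipsoid
  with a jittered cubic lattice (spacing ≈ 3.8 Å, the Cα–Cα distance), a
  snake chain path, clustered interior vacancies so local density varies,
  alternating helix/sheet/loop runs and two designated active-site residues.
  Interior points are buried, flat-face points are exposed yet densely
  contacted, void-adjacent points are buried yet sparse — so median
  binarization populates all 16 factorial bins.
* **MSAs** — Gibbs samples from a known Potts model (Boltzmann distribution
  over sequences), so Potts fitting can be checked against a ground truth.
* **activity landscapes** — additive per-position effects plus pairwise
  epistatic effects confined to one designated "hard" structural class;
  epistasis localized to a class is the mechanism hypothesized to make that
  class harder to predict.
* **screens** — variants dealt onto 96-well plates (94 variants + 2 blanks),
  measured in triplicate with Gaussian replicate noise (SD 7.55e-3 by
  default) on top of a per-plate background, blanks around the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, AA21_INDEX
from .design import VariantSpec
from .partitioning import CHARACTERISTICS, PositionPartition
from .potts import MSA, PottsModel
from .structure import Residue, StructureModel

__all__ = [
    "LandscapeParams",
    "SyntheticGroundTruth",
    "generate_toy_structure",
    "conserved_potts_model",
    "generate_potts_msa",
    "generate_activity_landscape",
    "simulate_screen",
]

CA_SPACING = 3.8  # Å, consecutive-residue Cα distance

#: Replicate noise matching the stain-removal screen's mean replicate SD.
DEFAULT_REPLICATE_SD = 7.55e-3
#: Blank noise sized so per-plate LOD = 3*sigma_blank lands near 1.09e-2.
DEFAULT_BLANK_SD = 3.9e-3


def generate_toy_structure(
    n_residues: int = 200,
    seed: int = 0,
    jitter: float = 0.35,
    aspect: float = 0.5,
    n_voids: int = 10,
    void_sigma: float = 1.2,
    void_strength: float = 1.0,
    void_center_frac: float = 0.45,
) -> tuple[StructureModel, pd.DataFrame]:
    """Build a compact globular Cα trace with known intended class labels.

    The globule is an oblate ellipsoid (z semi-axis ``aspect`` times the
    equatorial one) thinned by clustered interior vacancies ("voids"). Both
    choices decorrelate local packing density from depth: the flat faces
    carry exposed-but-densely-contacted positions, the voids carry
    buried-but-sparse ones. Without them buriedness and contact count would
    be nearly redundant and the discordant factorial bins would stay empty.

    Returns the structure and a per-position table of the labels the
    construction intends (``buried``, ``many_contacts``,
    ``close_to_active_site``, ``helix_or_sheet`` plus the active-site
    positions as attrs). The intended labels are derived from the pre-jitter
    lattice geometry (analytic distance to the ellipsoid surface, fixed-shell
    neighbor counts), independently of the feature computations they are
    meant to validate.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues")
    rng = np.random.default_rng(seed)

    # smallest ellipsoid holding enough lattice points after void thinning
    target = int(np.ceil(n_residues * 1.45))
    a = 1.0
    while True:
        m = int(np.ceil(a))
        c = a * aspect
        mz = int(np.ceil(c))
        grid = np.array(
            [
                (x, y, z)
                for x in range(-m, m + 1)
                for y in range(-m, m + 1)
                for z in range(-mz, mz + 1)
                if (x / a) ** 2 + (y / a) ** 2 + (z / c) ** 2 <= 1.0
            ],
            dtype=float,
        )
        if len(grid) >= target:
            break
        a += 0.25
    c = a * aspect

    # clustered vacancies: removal probability peaks near interior void centers,
    # thinning the core so that surface points can exceed the density median
    bound = np.array([a, a, c]) * void_center_frac
    void_centers = rng.uniform(-1.0, 1.0, size=(n_voids, 3)) * bound
    d2v = ((grid[:, None, :] - void_centers[None, :, :]) ** 2).sum(axis=2)
    p_remove = void_strength * np.exp(-d2v / (2.0 * void_sigma**2)).max(axis=1)
    survivors = np.flatnonzero(rng.random(len(grid)) > p_remove)
    if len(survivors) < n_residues:  # voids ate too much; backfill at random
        removed = np.setdiff1d(np.arange(len(grid)), survivors)
        refill = rng.permutation(removed)[: n_residues - len(survivors)]
        survivors = np.concatenate([survivors, refill])
    keep = rng.permutation(survivors)[:n_residues]
    pts = grid[np.sort(keep)]
    order = np.lexsort(
        (
            np.where(pts[:, 1].astype(int) % 2 == 0, pts[:, 0], -pts[:, 0]),
            np.where(pts[:, 2].astype(int) % 2 == 0, pts[:, 1], -pts[:, 1]),
            pts[:, 2],
        )
    )
    units = pts[order]
    lattice = units * CA_SPACING
    coords = lattice + rng.normal(0.0, jitter, size=lattice.shape)

    # intended labels from pre-jitter lattice geometry: first-order distance
    # to the ellipsoid surface, and neighbor counts at a fixed shell radius
    mval = np.sqrt((units[:, 0] / a) ** 2 + (units[:, 1] / a) ** 2 + (units[:, 2] / c) ** 2)
    gnorm = np.sqrt(
        (units[:, 0] / a**2) ** 2 + (units[:, 1] / a**2) ** 2 + (units[:, 2] / c**2) ** 2
    )
    depth = (1.0 - mval) / np.maximum(gnorm, 1e-9)
    buried = (depth > np.median(depth)).astype(int)
    d2 = ((lattice[:, None, :] - lattice[None, :, :]) ** 2).sum(axis=2)
    shell = (3.5 * CA_SPACING) ** 2  # roughly the derived contact radius
    density = (d2 <= shell).sum(axis=1) - 1
    many_contacts = (density > np.median(density)).astype(int)

    # two active sites: residues nearest two interior anchor points
    center = lattice.mean(axis=0)
    anchors = center + np.array([[0.5, 0.0, 0.0], [-0.5, 0.0, 0.0]]) * a * CA_SPACING
    site_idx = [int(np.argmin(np.linalg.norm(lattice - anchor, axis=1))) for anchor in anchors]
    if site_idx[0] == site_idx[1]:
        site_idx[1] = int(np.argsort(np.linalg.norm(lattice - anchors[1], axis=1))[1])
    site_dist = np.minimum(
        np.linalg.norm(lattice - lattice[site_idx[0]], axis=1),
        np.linalg.norm(lattice - lattice[site_idx[1]], axis=1),
    )
    close_to_active = (site_dist < np.median(site_dist)).astype(int)

    # alternating secondary-structure runs along the chain
    ss = np.zeros(n_residues, dtype=int)
    ss_records: list[tuple[str, int, int]] = []
    pos, kinds = 0, ("helix", "sheet")
    k = 0
    while pos < n_residues:
        run = 11 if kinds[k % 2] == "helix" else 10
        end = min(pos + run, n_residues)
        ss[pos:end] = 1
        ss_records.append((kinds[k % 2], pos + 1, end))
        pos = end + 10  # loop gap; keeps helix-or-sheet near half of positions
        k += 1

    aas = rng.choice(list(AA20), size=n_residues)
    residues = [
        Residue(position=i + 1, aa=str(aas[i]), ca=coords[i], atoms=coords[i][None, :].copy())
        for i in range(n_residues)
    ]
    model = StructureModel(residues=residues, ss_records=ss_records, chain_id="A")
    labels = pd.DataFrame(
        {
            "buried": buried,
            "many_contacts": many_contacts,
            "close_to_active_site": close_to_active,
            "helix_or_sheet": ss,
        },
        index=pd.RangeIndex(1, n_residues + 1, name="position"),
    )
    labels.attrs["active_sites"] = (site_idx[0] + 1, site_idx[1] + 1)
    return model, labels


def conserved_potts_model(
    reference: str,
    coupled_pairs: Sequence[tuple[int, int]] = (),
    conservation: float = 1.5,
    coupling_strength: float = 2.0,
    seed: int = 0,
) -> PottsModel:
    """A generating Potts model: fields biased toward a reference sequence,
    plus favored-combination couplings on the given 0-based position pairs."""
    rng = np.random.default_rng(seed)
    L, q = len(reference), 21
    h = rng.normal(0.0, 0.1, size=(L, q))
    for i, aa in enumerate(reference):
        h[i, AA21_INDEX[aa]] += conservation
    h[:, AA21_INDEX["-"]] -= 10.0  # freeze out the gap state
    W = np.zeros((L * q, L * q))
    for i, j in coupled_pairs:
        if not 0 <= i < j < L:
            raise ValueError(f"bad coupled pair ({i}, {j})")
        a, b = rng.integers(20), rng.integers(20)
        block = np.zeros((q, q))
        block[a, b] = coupling_strength
        W[i * q : (i + 1) * q, j * q : (j + 1) * q] = block
        W[j * q : (j + 1) * q, i * q : (i + 1) * q] = block.T
    return PottsModel(h=h, W=W)


def generate_potts_msa(
    model: PottsModel,
    n_sequences: int,
    burn_in: int = 200,
    thin: int = 5,
    seed: int = 0,
    n_chains: int | None = None,
) -> MSA:
    """Gibbs-sample sequences from the model's Boltzmann distribution.

    Runs parallel chains from random starts, discards ``burn_in`` full
    sweeps, then collects every ``thin`` sweeps from all chains until
    ``n_sequences`` are gathered. The gap state is excluded from proposals
    (sampled sequences are gapless homologs).
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    rng = np.random.default_rng(seed)
    L, q = model.L, model.q
    allowed = np.arange(20)  # no gap
    C = n_chains or min(n_sequences, 500)
    S = rng.integers(0, 20, size=(C, L))

    norms = model.coupling_norms()
    nbrs = [np.flatnonzero((norms[i] + norms[:, i]) > 0) for i in range(L)]
    h_allowed = model.h[:, allowed]

    def sweep() -> None:
        for i in range(L):
            logits = np.broadcast_to(h_allowed[i], (C, 20)).copy()
            for j in nbrs[i]:
                block = model.W[i * q : (i + 1) * q, j * q : (j + 1) * q][np.ix_(allowed, np.arange(q))]
                logits += block[:, S[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(C)
            S[:, i] = allowed[(p.cumsum(axis=1) < u[:, None]).sum(axis=1)]

    for _ in range(burn_in):
        sweep()
    collected: list[np.ndarray] = []
    while sum(len(c) for c in collected) < n_sequences:
        collected.append(S.copy())
        for _ in range(thin):
            sweep()
    states = np.concatenate(collected)[:n_sequences]
    seqs = ["".join(AA20[a] for a in row) for row in states]
    return MSA(seqs)


@dataclass
class LandscapeParams:
    """Defaults sized to the stain-removal screen's printed activity scale.

    Additive effects are Normal(additive_mean, additive_sd) per position by
    default. The mean dominates the spread: the average substitution is
    clearly deleterious, so a variant's activity is driven mostly by how many
    mutations it carries — a component every structural class shares — with
    smaller position-specific variation on top. This keeps additive-only
    classes statistically exchangeable, so class contrasts reflect injected
    interaction structure rather than which class happened to draw the more
    rankable landscape. ``"fixed_magnitude"`` draws additive_mean ±
    additive_sd with random signs instead (identical realized variance in
    every class).
    """

    baseline: float = 0.1  # wild-type activity, absorbance units
    additive_mean: float = -0.02  # the average substitution is clearly deleterious
    additive_sd: float = 0.007  # position-to-position variation around that mean
    additive_distribution: str = "normal"  # or "fixed_magnitude"
    epistasis_fraction: float = 0.5  # epistatic variance / additive variance
    alt_modulation_sd: float = 0.0  # >0 makes effects depend on the alt residue
    replicate_sd: float = DEFAULT_REPLICATE_SD
    blank_sd: float = DEFAULT_BLANK_SD


@dataclass
class SyntheticGroundTruth:
    """The generating truth behind a simulated screen."""

    labels: pd.DataFrame  # per-position binary class labels used
    hard_characteristic: str
    baseline: float
    position_effects: dict[int, float]
    epistatic_effects: dict[tuple[int, int], float]  # keys (i, j), i < j, both hard-positive
    alt_effects: dict[tuple[int, str], float] = field(default_factory=dict)
    replicate_sd: float = DEFAULT_REPLICATE_SD
    blank_sd: float = DEFAULT_BLANK_SD
    potts: PottsModel | None = None

    def activity(self, variant: VariantSpec) -> float:
        """Noiseless activity: baseline + additive sums + localized epistasis."""
        total = self.baseline
        positions = sorted(m.position for m in variant.mutations)
        for m in variant.mutations:
            total += self.position_effects[m.position]
            total += self.alt_effects.get((m.position, m.alt), 0.0)
        for a_idx in range(len(positions)):
            for b_idx in range(a_idx + 1, len(positions)):
                total += self.epistatic_effects.get((positions[a_idx], positions[b_idx]), 0.0)
        return total


def generate_activity_landscape(
    partition: PositionPartition,
    hard_characteristic: str,
    params: LandscapeParams | None = None,
    seed: int = 0,
) -> SyntheticGroundTruth:
    """Draw a landscape whose non-additive structure lives in one class.

    Additive effects are i.i.d. Normal(additive_mean, additive_sd) per
    position; pairwise epistatic effects Normal(0, additive_sd *
    sqrt(epistasis_fraction)) are drawn for every pair of positions positive
    for ``hard_characteristic`` and zero elsewhere.
    """
    params = params or LandscapeParams()
    if hard_characteristic not in CHARACTERISTICS:
        raise ValueError(f"unknown characteristic {hard_characteristic!r}")
    rng = np.random.default_rng(seed)
    positions = sorted(
        p for members in partition.bins.values() for p in members
    )
    hard = sorted(partition.positive_positions(hard_characteristic))
    if not hard:
        raise ValueError(f"hard class {hard_characteristic!r} is empty")
    if params.additive_distribution == "normal":
        position_effects = {
            p: float(rng.normal(params.additive_mean, params.additive_sd)) for p in positions
        }
    elif params.additive_distribution == "fixed_magnitude":
        signs = rng.choice((-1.0, 1.0), size=len(positions))
        position_effects = {
            p: float(params.additive_mean + s * params.additive_sd)
            for p, s in zip(positions, signs)
        }
    else:
        raise ValueError(f"unknown additive_distribution {params.additive_distribution!r}")
    epi_sd = params.additive_sd * np.sqrt(params.epistasis_fraction)
    epistatic: dict[tuple[int, int], float] = {}
    if epi_sd > 0:
        for a_idx in range(len(hard)):
            for b_idx in range(a_idx + 1, len(hard)):
                epistatic[(hard[a_idx], hard[b_idx])] = float(rng.normal(0.0, epi_sd))
    alt_effects: dict[tuple[int, str], float] = {}
    if params.alt_modulation_sd > 0:
        for p in positions:
            for aa in AA20:
                alt_effects[(p, aa)] = float(rng.normal(0.0, params.alt_modulation_sd))
    labels = pd.DataFrame(
        {
            char: [1 if p in partition.positive_positions(char) else 0 for p in positions]
            for char in CHARACTERISTICS
        },
        index=pd.Index(positions, name="position"),
    )
    return SyntheticGroundTruth(
        labels=labels,
        hard_characteristic=hard_characteristic,
        baseline=params.baseline,
        position_effects=position_effects,
        epistatic_effects=epistatic,
        alt_effects=alt_effects,
        replicate_sd=params.replicate_sd,
        blank_sd=params.blank_sd,
    )


def simulate_screen(
    library: Sequence[VariantSpec],
    truth: SyntheticGroundTruth,
    plate_size: int = 96,
    n_blanks: int = 2,
    n_replicates: int = 3,
    background: float = 0.05,
    background_jitter: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Deal variants onto plates and measure raw absorbances in triplicate.

    Each plate holds ``plate_size − n_blanks`` variants plus blank wells;
    every well value is plate background + (variant activity or 0) +
    Gaussian noise (``truth.replicate_sd`` for variants, ``truth.blank_sd``
    for blanks). Background cancels exactly under plate normalization.
    """
    if not library:
        raise ValueError("empty library")
    rng = np.random.default_rng(seed)
    per_plate = plate_size - n_blanks
    if per_plate < 1:
        raise ValueError("plate_size must exceed n_blanks")
    rep_cols = [f"rep{r + 1}" for r in range(n_replicates)]
    rows = []
    for start in range(0, len(library), per_plate):
        plate_id = f"P{start // per_plate + 1:03d}"
        bg = background + rng.normal(0.0, background_jitter)
        for offset, variant in enumerate(library[start : start + per_plate]):
            act = truth.activity(variant)
            reps = bg + act + rng.normal(0.0, truth.replicate_sd, size=n_replicates)
            rows.append(
                {
                    "variant_id": f"v{start + offset:05d}",
                    "mutations": ";".join(
                        str(m) for m in sorted(variant.mutations)
                    ),
                    "plate": plate_id,
                    **dict(zip(rep_cols, reps)),
                    "is_blank": False,
                }
            )
        for b in range(n_blanks):
            reps = bg + rng.normal(0.0, truth.blank_sd, size=n_replicates)
            rows.append(
                {
                    "variant_id": f"{plate_id}_blank{b + 1}",
                    "mutations": "",
                    "plate": plate_id,
                    **dict(zip(rep_cols, reps)),
                    "is_blank": True,
                }
            )
    return pd.DataFrame(rows)
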