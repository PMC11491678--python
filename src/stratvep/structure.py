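"""Per-residue structural characteristics of an enzyme.

Four characteristics drive the stratified analysis:

* **buriedness** — shortest distance from any of the residue's heavy atoms to
  the convex hull of all heavy atoms of the protein (Å; 0 on the hull);
* **number of contacts** — count of other Cα atoms within a cutoff radius of
  the residue's Cα, the radius being derived from the chain geometry itself
  (mean consecutive Cα–Cα distance plus two standard deviations);
* **distance to the active site** — minimum Cα–Cα distance to the catalytic
  residues (for the B. subtilis alpha-amylase, D176 and E208);
* **secondary structure** — whether the position lies in a helix or sheet, as
  annotated by the structure file's HELIX/SHEET records (turns count as loop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

__all__ = [
    "Residue",
    "StructureModel",
    "StructuralProfile",
    "read_structure",
    "write_structure",
    "compute_buriedness",
    "derive_contact_radius",
    "count_contacts",
    "active_site_distance",
    "assign_secondary_structure",
    "build_profile",
]

_ATOM_NAMES = ["CA", "CB", "CG", "CD", "CE", "CZ", "CH", "CT", "CU", "CV", "CW", "CX"]


@dataclass(frozen=True)
class Residue:
    position: int  # 1-based mature-sequence position
    aa: str  # one-letter code ("X" for unknown)
    ca: np.ndarray  # (3,) Å
    atoms: np.ndarray  # (k, 3) heavy-atom coordinates, Å; includes Cα


@dataclass
class StructureModel:
    residues: list[Residue]
    ss_records: list[tuple[str, int, int]] = field(default_factory=list)
    chain_id: str = "A"

    def __post_init__(self) -> None:
        pos = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("residue positions must be strictly increasing")
        for r in self.residues:
            if r.ca is None or np.asarray(r.ca).shape != (3,):
                raise ValueError(f"residue {r.position} lacks a Cα coordinate")
        lo, hi = (min(pos), max(pos)) if pos else (0, -1)
        for kind, start, end in self.ss_records:
            if kind not in ("helix", "sheet"):
                raise ValueError(f"unknown secondary-structure kind {kind!r}")
            if start > end or start < lo or end > hi:
                raise ValueError(f"ss record ({kind}, {start}, {end}) outside residue range")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.position for r in self.residues], dtype=int)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.stack([r.ca for r in self.residues]) if self.residues else np.empty((0, 3))

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def index_of(self, position: int) -> int:
        idx = int(np.searchsorted(self.positions, position))
        if idx >= len(self) or self.residues[idx].position != position:
            raise KeyError(f"position {position} not in structure")
        return idx

    def heavy_atoms(self) -> np.ndarray:
        return np.concatenate([r.atoms for r in self.residues])


def _pick_altloc(res: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """Keep, per atom name, the highest-occupancy alternative conformation."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return best


def read_structure(path: str | Path, chain: str | None = None, offset: int = 0) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    chain
        Chain id to extract; the first chain when omitted.
    offset
        Added to PDB residue numbers to obtain 1-based mature-sequence
        positions (crystal structures are frequently numbered against a
        precursor or have leading disorder).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models/ATOM records")
    model = st[0]
    chain_ids = [ch.name for ch in model]
    if not chain_ids:
        raise ValueError(f"{path}: no chains")
    if chain is None:
        chain = chain_ids[0]
    elif chain not in chain_ids:
        raise ValueError(f"chain {chain!r} not in {path} (has {chain_ids})")
    gchain = model[chain]

    residues: list[Residue] = []
    skipped: list[int] = []
    for res in gchain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        atoms = _pick_altloc(res)
        heavy = np.array(
            [[a.pos.x, a.pos.y, a.pos.z] for a in atoms.values() if not a.element.is_hydrogen],
            dtype=float,
        )
        ca = atoms.get("CA")
        if ca is None or heavy.size == 0:
            skipped.append(res.seqid.num)
            continue
        aa = gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
        if not aa.isalpha():
            aa = "X"
        residues.append(
            Residue(
                position=res.seqid.num + offset,
                aa=aa,
                ca=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                atoms=heavy,
            )
        )
    if not residues:
        raise ValueError(f"{path}: chain {chain} has no amino-acid ATOM records")
    if skipped:
        warnings.warn(f"{path}: excluded {len(skipped)} residue(s) lacking Cα: {skipped[:10]}")

    present = {r.position for r in residues}

    def _clip(kind: str, start: int, end: int) -> tuple[str, int, int] | None:
        covered = sorted(p for p in present if start <= p <= end)
        return (kind, covered[0], covered[-1]) if covered else None

    ss: list[tuple[str, int, int]] = []
    for helix in st.helices:
        if helix.start.chain_name == chain:
            rec = _clip("helix", helix.start.res_id.seqid.num + offset, helix.end.res_id.seqid.num + offset)
            if rec:
                ss.append(rec)
    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name == chain:
                rec = _clip("sheet", strand.start.res_id.seqid.num + offset, strand.end.res_id.seqid.num + offset)
                if rec:
                    ss.append(rec)
    return StructureModel(residues=residues, ss_records=ss, chain_id=chain)


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as a minimal PDB file (via gemmi).

    Atom names are synthetic: the Cα is written as CA, further heavy atoms get
    generic carbon names, so a round trip preserves coordinates and records
    but not chemistry.
    """
    st = gemmi.Structure()
    st.name = "stratvep"
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain(model.chain_id)
    for r in model.residues:
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(r.aa, "UNK")
        res.seqid = gemmi.SeqId(r.position, " ")
        # order atoms so that the Cα comes first
        coords = [r.ca] + [a for a in r.atoms if not np.array_equal(a, r.ca)]
        for k, xyz in enumerate(coords):
            atom = gemmi.Atom()
            atom.name = _ATOM_NAMES[k] if k < len(_ATOM_NAMES) else f"C{k}"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    gmodel.add_chain(chain)
    st.add_model(gmodel)
    for kind, start, end in model.ss_records:
        start_res = _ONE_TO_THREE.get(model.residues[model.index_of(start)].aa, "UNK")
        end_res = _ONE_TO_THREE.get(model.residues[model.index_of(end)].aa, "UNK")
        a0 = gemmi.AtomAddress(model.chain_id, gemmi.SeqId(start, " "), start_res, "")
        a1 = gemmi.AtomAddress(model.chain_id, gemmi.SeqId(end, " "), end_res, "")
        if kind == "helix":
            helix = gemmi.Helix()
            helix.start, helix.end = a0, a1
            st.helices.append(helix)
        else:
            strand = gemmi.Sheet.Strand()
            strand.start, strand.end = a0, a1
            sheet = gemmi.Sheet("S")
            sheet.strands.append(strand)
            st.sheets.append(sheet)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def _hull_plane_distances(points: np.ndarray, hull: ConvexHull) -> np.ndarray:
    """Distance of each point to its nearest hull facet plane (0 on the hull)."""
    # hull.equations rows are (normal, offset) with outward unit normals:
    # normal @ x + offset <= 0 inside.
    signed = points @ hull.equations[:, :3].T + hull.equations[:, 3]
    return np.maximum(-signed.max(axis=1), 0.0)


def compute_buriedness(model: StructureModel, position: int, _hull: ConvexHull | None = None) -> float:
    """Buriedness of one residue: min heavy-atom distance to the convex hull.

    The hull is taken over all heavy atoms of the structure; the distance is
    to the nearest facet plane, so hull vertices score exactly 0.
    """
    cloud = model.heavy_atoms()
    if len(cloud) < 4:
        raise ValueError("need at least 4 atoms for a 3D convex hull")
    try:
        hull = _hull if _hull is not None else ConvexHull(cloud)
    except Exception as exc:  # scipy QhullError on degenerate clouds
        raise ValueError(f"degenerate atom cloud, no 3D hull: {exc}") from exc
    atoms = model.residues[model.index_of(position)].atoms
    return float(_hull_plane_distances(atoms, hull).min())


def derive_contact_radius(model: StructureModel) -> float:
    """Cutoff radius = mean + 2·SD of consecutive Cα–Cα distances.

    "Neighboring" Cα atoms are consecutive residues in sequence order; the SD
    is the sample standard deviation (n−1 denominator).
    """
    if len(model) < 3:
        raise ValueError("need at least 3 residues to derive a contact radius")
    ca = model.ca_coords
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    return float(d.mean() + 2.0 * d.std(ddof=1))


def count_contacts(model: StructureModel, position: int, radius: float) -> int:
    """Number of other residues whose Cα lies within ``radius`` of the focal Cα."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    i = model.index_of(position)
    d = np.linalg.norm(model.ca_coords - model.residues[i].ca, axis=1)
    d[i] = np.inf  # exclude self
    return int((d <= radius).sum())


def active_site_distance(model: StructureModel, position: int, active_sites: list[int]) -> float:
    """Minimum Cα–Cα distance from the focal residue to any active-site residue."""
    if not active_sites:
        raise ValueError("active_sites must be non-empty")
    focal = model.residues[model.index_of(position)].ca
    site_ca = np.stack([model.residues[model.index_of(p)].ca for p in active_sites])
    return float(np.linalg.norm(site_ca - focal, axis=1).min())


def assign_secondary_structure(
    model: StructureModel, override: dict[int, int] | None = None
) -> pd.Series:
    """Binary helix-or-sheet labels per position from HELIX/SHEET records.

    ``override`` maps positions to explicit 0/1 labels and takes precedence
    (e.g. from an external assignment tool).
    """
    labels = pd.Series(0, index=model.positions, dtype=int)
    for _kind, start, end in model.ss_records:
        labels.loc[(labels.index >= start) & (labels.index <= end)] = 1
    if override:
        unknown = set(override) - set(labels.index)
        if unknown:
            raise ValueError(f"override positions absent from structure: {sorted(unknown)[:10]}")
        for pos, lab in override.items():
            labels.loc[pos] = int(bool(lab))
    labels.index.name = "position"
    return labels


@dataclass
class StructuralProfile:
    """Continuous per-residue characteristics plus the derived contact radius."""

    table: pd.DataFrame  # index: position; columns: aa, buriedness, n_contacts, active_site_distance, ss
    contact_radius: float
    active_sites: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | Path) -> None:
        df = self.table.copy()
        df.insert(0, "position", df.index)
        with open(path, "w") as fh:
            fh.write(f"# contact_radius={self.contact_radius:.6f}\n")
            fh.write(f"# active_sites={','.join(map(str, self.active_sites))}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StructuralProfile":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos0 = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val
                    pos0 = fh.tell()
                else:
                    fh.seek(pos0)
                    break
            df = pd.read_csv(fh)
        df = df.set_index("position")
        sites = tuple(int(s) for s in meta.get("active_sites", "").split(",") if s)
        return cls(table=df, contact_radius=float(meta["contact_radius"]), active_sites=sites)


def build_profile(
    model: StructureModel,
    active_sites: list[int],
    ss_override: dict[int, int] | None = None,
) -> StructuralProfile:
    """Assemble all four structural characteristics for every residue."""
    radius = derive_contact_radius(model)
    hull = ConvexHull(model.heavy_atoms())
    ss = assign_secondary_structure(model, override=ss_override)
    rows = []
    for r in model.residues:
        rows.append(
            {
                "aa": r.aa,
                "buriedness": float(_hull_plane_distances(r.atoms, hull).min()),
                "n_contacts": count_contacts(model, r.position, radius),
                "active_site_distance": active_site_distance(model, r.position, active_sites),
                "ss": int(ss.loc[r.position]),
            }
        )
    table = pd.DataFrame(rows, index=model.positions)
    table.index.name = "position"
    return StructuralProfile(table=table, contact_radius=radius, active_sites=tuple(active_sites))
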