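"""Structure I/O and Fe-S site geometry.

Reads PDB files into lightweight domain objects, locates rubredoxin-type
mononuclear Fe and binuclear [2Fe-2S] cofactor sites, and answers the
spherical neighborhood queries every descriptor is built on.

Conventions fixed here (and relied on throughout the package):

* model 1 only; hydrogens, waters and alternate locations other than the
  highest-occupancy one are discarded (occupancy ties break by altloc
  letter, 'A' first);
* cofactor atoms are the metal ions and inorganic bridging sulfides of the
  FES / FE hetero group only -- cysteine thiolate sulfurs are residue atoms;
* a residue "coordinates" the cluster when any of its side-chain atoms lies
  within ``BOND_CUTOFF`` (3.0 A) of an Fe ion, which covers Fe-S(Cys)
  (~2.3 A) and Fe-N(His) (~2.1 A) with margin;
* neighborhood membership uses the any-atom rule with an inclusive
  boundary by default (configurable to C-alpha or side-chain centroid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "ClusterSite",
    "StructureError",
    "read_pdb",
    "detect_cluster_sites",
    "barycenter",
    "residues_within",
    "BOND_CUTOFF",
]

#: Fe--ligand bond cutoff (A) used to call coordinating residues.
BOND_CUTOFF = 3.0

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Hetero residue names recognized as the focal cofactor groups.
FES_CODES = {"FES"}
MONO_FE_CODES = {"FE", "FE2"}


class StructureError(ValueError):
    """Raised for unreadable files, empty structures or missing cofactors."""


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    residue_key: tuple  # (chain id, residue number, insertion code)
    het_flag: bool
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(f"atom {self.atom_name}: bad coordinates {self.coords}")
        if not self.element:
            raise StructureError(f"atom {self.atom_name}: empty element")
        object.__setattr__(self, "coords", c)


@dataclass(frozen=True)
class Residue:
    three_letter_code: str
    residue_key: tuple
    atoms: tuple  # tuple of AtomRecord
    is_standard_aa: bool

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise StructureError(f"residue {self.three_letter_code} {self.residue_key}: no atoms")

    @property
    def coord_array(self) -> np.ndarray:
        return np.stack([a.coords for a in self.atoms])

    def side_chain_atoms(self) -> tuple:
        sc = tuple(a for a in self.atoms if a.atom_name not in BACKBONE_ATOMS)
        return sc if sc else self.atoms  # Gly: fall back to all atoms


@dataclass
class Structure:
    id: str
    residues: list  # ordered standard (polymer) residues
    hetero_groups: list  # non-water hetero residues
    resolution: float | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _tree_map: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        seen = set()
        for r in self.residues:
            if r.residue_key in seen:
                raise StructureError(f"duplicate residue key {r.residue_key}")
            seen.add(r.residue_key)

    def _atom_index(self):
        """KD-tree over all standard-residue atoms (lazy, cached)."""
        if self._tree is None:
            coords, owner = [], []
            for i, res in enumerate(self.residues):
                for a in res.atoms:
                    coords.append(a.coords)
                    owner.append(i)
            if not coords:
                raise StructureError(f"structure {self.id}: no standard residues")
            self._tree = cKDTree(np.asarray(coords))
            self._tree_map = np.asarray(owner)
        return self._tree, self._tree_map


@dataclass
class ClusterSite:
    site_kind: Literal["mono_fe", "fe2s2"]
    cofactor_atoms: list  # list of (element, coords) with element in {"FE","S"}
    coordinating_residues: list  # list of (Residue, AtomRecord, float distance)
    barycenter: np.ndarray
    residue_key: tuple | None = None  # key of the source hetero group

    def fe_coords(self) -> np.ndarray:
        return np.stack([c for e, c in self.cofactor_atoms if e == "FE"])

    def s_coords(self) -> np.ndarray:
        cs = [c for e, c in self.cofactor_atoms if e == "S"]
        return np.stack(cs) if cs else np.empty((0, 3))


# ---------------------------------------------------------------------------
# Parsing

def _pick_altloc(atoms: Sequence) -> object:
    """Highest occupancy wins; ties break by altloc letter ascending."""
    return sorted(atoms, key=lambda a: (-(a.occupancy if a.occupancy is not None else 0.0),
                                        a.altloc))[0]


def read_pdb(path: str | Path, structure_id: str | None = None) -> Structure:
    """Parse a PDB file into a :class:`Structure` (model 1 only).

    Hydrogens and waters are dropped; alternate locations resolve to the
    highest-occupancy conformer. Crystallographic resolution is taken from
    the header (REMARK 2) when present.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure(structure_id or path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    models = list(bio)
    if not models:
        raise StructureError(f"{path}: empty structure")
    model = models[0]

    resolution = None
    header = getattr(bio, "header", None) or {}
    if header.get("resolution") is not None:
        try:
            resolution = float(header["resolution"])
        except (TypeError, ValueError):
            resolution = None

    residues: list[Residue] = []
    hetero: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, resnum, icode = res.id
            resname = res.get_resname().strip()
            if resname in {"HOH", "WAT", "DOD"}:
                continue
            atoms = []
            for atom in res:
                group = atom.disordered_get_list() if atom.is_disordered() else [atom]
                chosen = _pick_altloc(group)
                element = (chosen.element or "").strip().upper()
                if element == "H" or chosen.get_name().startswith("H"):
                    continue
                atoms.append(AtomRecord(
                    atom_name=chosen.get_name().strip(),
                    element=element or chosen.get_name().strip()[0],
                    coords=np.asarray(chosen.get_coord(), dtype=float),
                    residue_key=(chain.id, resnum, icode.strip()),
                    het_flag=bool(hetflag.strip()),
                    altloc=chosen.get_altloc().strip(),
                    occupancy=float(chosen.get_occupancy() or 1.0),
                ))
            if not atoms:
                continue
            domain_res = Residue(
                three_letter_code=resname,
                residue_key=(chain.id, resnum, icode.strip()),
                atoms=tuple(atoms),
                is_standard_aa=resname in STANDARD_AA,
            )
            if hetflag.strip():
                hetero.append(domain_res)
            elif domain_res.is_standard_aa:
                residues.append(domain_res)
            else:
                hetero.append(domain_res)  # modified residues treated as hetero

    if not residues and not hetero:
        raise StructureError(f"{path}: no ATOM/HETATM records parsed")
    residues.sort(key=lambda r: (r.residue_key[0], r.residue_key[1], r.residue_key[2]))
    return Structure(id=structure_id or path.stem, residues=residues,
                     hetero_groups=hetero, resolution=resolution)


# ---------------------------------------------------------------------------
# Cofactor sites

def _site_from_group(group: Residue, structure: Structure) -> ClusterSite:
    cof = []
    for a in group.atoms:
        el = a.element.upper()
        if el == "FE":
            cof.append(("FE", a.coords))
        elif el == "S":
            cof.append(("S", a.coords))
    n_fe = sum(1 for e, _ in cof if e == "FE")
    n_s = len(cof) - n_fe
    if group.three_letter_code in FES_CODES:
        if (n_fe, n_s) != (2, 2):
            raise StructureError(
                f"{structure.id}: FES group {group.residue_key} has {n_fe} Fe / {n_s} S")
        kind = "fe2s2"
    else:
        if (n_fe, n_s) != (1, 0):
            raise StructureError(
                f"{structure.id}: FE group {group.residue_key} has {n_fe} Fe / {n_s} S")
        kind = "mono_fe"

    fe_coords = np.stack([c for e, c in cof if e == "FE"])
    coordinating = []
    for res in structure.residues:
        best = None
        for atom in res.side_chain_atoms():
            d = float(np.min(np.linalg.norm(fe_coords - atom.coords, axis=1)))
            if d <= BOND_CUTOFF and (best is None or d < best[2]):
                best = (res, atom, d)
        if best is not None:
            coordinating.append(best)
    bc = np.mean(np.stack([c for _, c in cof]), axis=0)
    return ClusterSite(site_kind=kind, cofactor_atoms=cof,
                       coordinating_residues=coordinating, barycenter=bc,
                       residue_key=group.residue_key)


def detect_cluster_sites(structure: Structure,
                         selector: tuple | None = None) -> list[ClusterSite]:
    """Locate [2Fe-2S] (FES) and mononuclear Fe cofactor sites.

    ``selector`` is an optional ``(chain id, residue number)`` pair naming a
    single hetero group; only that site is then returned.
    """
    sites = []
    for group in structure.hetero_groups:
        if group.three_letter_code in FES_CODES | MONO_FE_CODES:
            sites.append(_site_from_group(group, structure))
    if selector is not None:
        chain, resnum = selector
        matched = [s for s in sites
                   if s.residue_key[0] == chain and s.residue_key[1] == int(resnum)]
        if not matched:
            raise StructureError(
                f"{structure.id}: selector {selector!r} matches no cofactor site")
        return matched
    if not sites:
        raise StructureError(f"{structure.id}: no Fe-S cofactor found")
    return sites


def barycenter(site: ClusterSite) -> np.ndarray:
    """Unweighted mean of the cofactor atom coordinates."""
    return np.mean(np.stack([c for _, c in site.cofactor_atoms]), axis=0)


# ---------------------------------------------------------------------------
# Neighborhood queries

AssignmentRule = Literal["any_atom", "ca", "sidechain_centroid"]


def _residue_anchor(res: Residue, rule: AssignmentRule) -> np.ndarray | None:
    if rule == "ca":
        for a in res.atoms:
            if a.atom_name == "CA":
                return a.coords
        return None
    if rule == "sidechain_centroid":
        return np.mean(np.stack([a.coords for a in res.side_chain_atoms()]), axis=0)
    raise ValueError(f"unknown assignment rule {rule!r}")


def residues_within(structure: Structure, center: np.ndarray, radius: float,
                    assignment_rule: AssignmentRule = "any_atom") -> list:
    """Standard residues assigned to the sphere of ``radius`` around ``center``.

    Default any-atom rule: a residue belongs to the sphere iff any of its
    atoms lies within ``radius`` (boundary inclusive). Cofactor hetero groups
    never participate. Returns residues in structure order.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    center = np.asarray(center, dtype=float)
    if assignment_rule == "any_atom":
        tree, owner = structure._atom_index()
        hit = tree.query_ball_point(center, r=radius)
        idx = sorted(set(owner[i] for i in hit))
        return [structure.residues[i] for i in idx]
    out = []
    for res in structure.residues:
        anchor = _residue_anchor(res, assignment_rule)
        if anchor is not None and np.linalg.norm(anchor - center) <= radius:
            out.append(res)
    return out


def residues_within_any(structure: Structure, centers: Iterable[np.ndarray],
                        radius: float,
                        assignment_rule: AssignmentRule = "any_atom") -> list:
    """Union of ``residues_within`` over several centers, in structure order."""
    keys = set()
    for c in centers:
        for res in residues_within(structure, c, radius, assignment_rule):
            keys.add(res.residue_key)
    return [r for r in structure.residues if r.residue_key in keys]
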