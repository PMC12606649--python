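"""Synthetic toy structures and reduction-potential data sets.

The toy-structure generator emits small but format-valid PDB models built
around a real cofactor geometry: a planar [2Fe-2S] rhombus (Fe-Fe 2.7 A,
Fe-S 2.2 A) or a single Fe ion, four ligating Cys/His residues with their
ligating atom at 2.3 A from an Fe, and further residues placed on radial
shells at exactly known distances from the cluster barycenter. Because
every atom position is constructed, the generator also returns the
ground-truth distance table that the geometry oracles test against.

The data-set generator builds a cohort of such proteins (wild type plus
point mutants realized as residue-code substitutions at fixed coordinates)
and assigns each entry a reduction potential from a known linear model over
named schema features, RP = sum_j w_j z_j + eps, with z_j the feature
standardized over the cohort and eps ~ Normal(0, sigma). Weights are
therefore in mV per population-sd of the feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import descriptors as D
from .datasetio import DatasetEntry
from .structio import AtomRecord, Residue, Structure

__all__ = [
    "ToyStructureSpec",
    "SyntheticRPSpec",
    "ToyStructure",
    "SyntheticDataset",
    "make_toy_structure",
    "make_synthetic_dataset",
    "structure_to_pdb",
]

MIN_ATOM_SEPARATION = 0.8  # A; closer placements are rejected

# [2Fe-2S] core geometry: Fe at +-x, bridging sulfides at +-y.
_FE_HALF_SEP = 1.35  # Fe-Fe 2.7 A
_FE_S_BOND = 2.2
_S_HALF = float(np.sqrt(_FE_S_BOND ** 2 - _FE_HALF_SEP ** 2))
_LIGAND_BOND = 2.3  # Fe-S(gamma) / Fe-N(delta)

_LIGATING_ATOM = {"CYS": ("SG", "S"), "HIS": ("ND1", "N")}
_SIDECHAIN_ATOM = {
    "CYS": ("SG", "S"), "HIS": ("ND1", "N"), "SER": ("OG", "O"),
    "THR": ("OG1", "O"), "ASP": ("OD1", "O"), "GLU": ("OE1", "O"),
    "ASN": ("ND2", "N"), "GLN": ("NE2", "N"), "LYS": ("NZ", "N"),
    "ARG": ("NH1", "N"), "MET": ("SD", "S"), "TYR": ("OH", "O"),
}


@dataclass(frozen=True)
class ToyStructureSpec:
    site_kind: str = "fe2s2"  # "mono_fe" | "fe2s2"
    sequence: tuple = ("CYS", "CYS", "CYS", "CYS", "GLY", "ALA", "SER")
    n_ligands: int = 4
    shells: tuple = (4.5, 9.5, 12.5)  # A, one per non-ligand residue
    extra_cofactors: tuple = ()  # ((code, distance A), ...)
    resolution: float = 1.5
    seed: int = 0
    structure_id: str = "toy"

    def __post_init__(self):
        if self.site_kind not in ("mono_fe", "fe2s2"):
            raise ValueError(f"unknown site kind {self.site_kind!r}")
        if len(self.shells) != len(self.sequence) - self.n_ligands:
            raise ValueError("need one shell radius per non-ligand residue")
        if any(s <= 0 for s in self.shells):
            raise ValueError("shell radii must be positive")
        for code in self.sequence[:self.n_ligands]:
            if code not in _LIGATING_ATOM:
                raise ValueError(f"ligand residues must be CYS or HIS, got {code}")


@dataclass
class ToyStructure:
    structure: Structure
    pdb_text: str
    ground_truth: dict  # residue_key -> {"barycenter": d, "cofactor_atoms": [d,...]}
    spec: ToyStructureSpec


def _unit_directions(n: int, rng: np.random.Generator, jitter: float = 0.2):
    """Well-spread unit vectors (golden spiral) with a small seeded jitter."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / max(n, 1)
    r = np.sqrt(np.maximum(0.0, 1.0 - z ** 2))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    dirs = dirs + rng.normal(0.0, jitter / 4.0, size=dirs.shape)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def _residue_atoms(code: str, direction: np.ndarray, anchor_dist: float,
                   anchor_is_sidechain: bool, key: tuple):
    """Atoms of one residue along a ray; the anchor atom sits at anchor_dist.

    With ``anchor_is_sidechain`` the side-chain atom is innermost (ligating
    residues point their Sg/Nd at the metal); otherwise the backbone N is the
    innermost atom, so the residue's nearest-atom distance equals the shell.
    """
    sc = _SIDECHAIN_ATOM.get(code)
    names: list[tuple[str, str]] = []
    if anchor_is_sidechain:
        assert sc is not None
        names = [sc, ("CB", "C"), ("CA", "C"), ("N", "N"), ("C", "C"), ("O", "O")]
    else:
        names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
        if code != "GLY":
            names.append(("CB", "C"))
        if sc is not None:
            names.append(sc)
    atoms = []
    for k, (name, element) in enumerate(names):
        coords = direction * (anchor_dist + 0.9 * k)
        atoms.append(AtomRecord(atom_name=name, element=element, coords=coords,
                                residue_key=key, het_flag=False))
    return atoms


def _check_separation(residues: Sequence[Residue]):
    coords = np.concatenate([r.coord_array for r in residues])
    if len(coords) < 2:
        return
    from scipy.spatial.distance import pdist
    dmin = float(pdist(coords).min())
    if dmin < MIN_ATOM_SEPARATION:
        raise ValueError(f"impossible placement: atoms {dmin:.2f} A apart "
                         f"(< {MIN_ATOM_SEPARATION} A)")


def make_toy_structure(spec: ToyStructureSpec,
                       path: str | Path | None = None) -> ToyStructure:
    """Build a toy Fe-S protein with fully known geometry.

    Returns the parsed-equivalent Structure, its PDB text (optionally written
    to ``path``) and the ground-truth per-residue distances to the cluster
    barycenter and to every cofactor atom.
    """
    rng = np.random.default_rng(spec.seed)

    if spec.site_kind == "fe2s2":
        cof = [("FE1", "FE", np.array([_FE_HALF_SEP, 0.0, 0.0])),
               ("FE2", "FE", np.array([-_FE_HALF_SEP, 0.0, 0.0])),
               ("S1", "S", np.array([0.0, _S_HALF, 0.0])),
               ("S2", "S", np.array([0.0, -_S_HALF, 0.0]))]
        het_name = "FES"
    else:
        cof = [("FE", "FE", np.zeros(3))]
        het_name = "FE"
    fe_positions = [c for _, e, c in cof if e == "FE"]

    n_res = len(spec.sequence)
    base_dirs = _unit_directions(n_res, rng)

    def _rays(dirs):
        """(direction, innermost distance) per residue for a direction set."""
        rays = []
        for i in range(n_res):
            if i < spec.n_ligands:
                fe = fe_positions[i % len(fe_positions)]
                d = dirs[i]
                outward = d if np.dot(d, fe) >= 0 or spec.site_kind == "mono_fe" else -d
                anchor = fe + outward * _LIGAND_BOND
                dist = float(np.linalg.norm(anchor))
                rays.append((anchor / dist, dist))
            else:
                rays.append((dirs[i], float(spec.shells[i - spec.n_ligands])))
        return rays

    # Spiral directions are ordered pole-to-pole; a seeded shuffle (with
    # retries) keeps same-shell residues angularly apart. The accepted
    # permutation is chosen on a worst-case 6-atom footprint per ray, so it
    # depends only on ligand count, shells and seed -- never on residue
    # codes. Point substitutions therefore keep coordinates fixed.
    chosen_rays = None
    dmin = 0.0
    for _attempt in range(20):
        dirs = base_dirs[rng.permutation(n_res)]
        rays = _rays(dirs)
        pts = np.concatenate([[d * (t + 0.9 * k) for k in range(6)]
                              for d, t in rays])
        from scipy.spatial.distance import pdist
        dmin = float(pdist(pts).min())
        if dmin >= MIN_ATOM_SEPARATION:
            chosen_rays = rays
            break
    if chosen_rays is None:
        raise ValueError(f"impossible placement: atoms {dmin:.2f} A apart "
                         f"(< {MIN_ATOM_SEPARATION} A)")

    residues: list[Residue] = []
    for i, code in enumerate(spec.sequence):
        key = ("A", i + 1, "")
        direction, dist = chosen_rays[i]
        atoms = _residue_atoms(code, direction, dist, i < spec.n_ligands, key)
        residues.append(Residue(three_letter_code=code, residue_key=key,
                                atoms=tuple(atoms), is_standard_aa=True))
    _check_separation(residues)

    hetero = [Residue(
        three_letter_code=het_name, residue_key=("A", 901, ""),
        atoms=tuple(AtomRecord(atom_name=n, element=e, coords=c,
                               residue_key=("A", 901, ""), het_flag=True)
                    for n, e, c in cof),
        is_standard_aa=False)]
    extra_dirs = _unit_directions(max(len(spec.extra_cofactors), 1), rng)
    for j, (code, dist) in enumerate(spec.extra_cofactors):
        key = ("A", 902 + j, "")
        axis = extra_dirs[j] * float(dist)
        hetero.append(Residue(
            three_letter_code=code, residue_key=key,
            atoms=(AtomRecord(atom_name="C1", element="C", coords=axis,
                              residue_key=key, het_flag=True),),
            is_standard_aa=False))

    structure = Structure(id=spec.structure_id, residues=residues,
                          hetero_groups=hetero, resolution=spec.resolution)

    bary = np.mean(np.stack([c for _, _, c in cof]), axis=0)
    ground_truth = {}
    for res in residues:
        ca = res.coord_array
        ground_truth[res.residue_key] = {
            "barycenter": float(np.min(np.linalg.norm(ca - bary, axis=1))),
            "cofactor_atoms": [float(np.min(np.linalg.norm(ca - c, axis=1)))
                               for _, _, c in cof],
        }

    text = structure_to_pdb(structure)
    if path is not None:
        Path(path).write_text(text)
    return ToyStructure(structure=structure, pdb_text=text,
                        ground_truth=ground_truth, spec=spec)


def _pdb_atom_name(name: str) -> str:
    return f" {name:<3}" if len(name) < 4 else name[:4]


def structure_to_pdb(structure: Structure) -> str:
    """Render a Structure as column-exact PDB text (ATOM/HETATM/REMARK 2)."""
    lines = [f"HEADER    SYNTHETIC FE-S TOY STRUCTURE            {'':>9}   {structure.id[:4].upper():<4}"]
    if structure.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.  {structure.resolution:6.2f} ANGSTROMS.")
    serial = 1
    for res in list(structure.residues) + list(structure.hetero_groups):
        record = "HETATM" if res.atoms[0].het_flag else "ATOM  "
        chain, resnum, icode = res.residue_key
        for a in res.atoms:
            x, y, z = a.coords
            lines.append(
                f"{record}{serial:>5} {_pdb_atom_name(a.atom_name)} "
                f"{res.three_letter_code:>3} {chain}{resnum:>4}{icode or ' ':1}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Synthetic RP data sets

#: Default generative support: condition, long-, medium- and short-scale
#: features chosen as weakly collinear representatives of their blocks, so
#: the planted signal is identifiable; weights in mV per population-sd.
DEFAULT_SUPPORT = ("Global.pH", "Protein.FlexibilityMin", "Bar.GlyProCount",
                   "CofAtom.Fe.2.HydrophobicCount", "Protein.AromaticCount")
DEFAULT_WEIGHTS = (-60.0, 45.0, -80.0, -70.0, 50.0)


@dataclass(frozen=True)
class SyntheticRPSpec:
    n_proteins: int = 50
    mutants_per_protein: int = 5
    support: tuple = DEFAULT_SUPPORT
    weights: tuple = DEFAULT_WEIGHTS
    sigma: float = 20.0  # mV
    ph_range: tuple = (5.0, 9.0)
    ref_r1: float = 11.0
    ref_r2: float = 4.0
    mono_fe_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if len(self.weights) != len(self.support):
            raise ValueError("one weight per support feature")

    @property
    def n_entries(self) -> int:
        return self.n_proteins * (1 + self.mutants_per_protein)


@dataclass
class SyntheticDataset:
    entries: list  # list of DatasetEntry
    structures: dict  # structure_ref -> Structure
    spec: SyntheticRPSpec
    feature_means: np.ndarray
    feature_sds: np.ndarray
    schema: D.FeatureSchema

    def true_rp(self, raw_support_values: np.ndarray) -> np.ndarray:
        """Noise-free RP for raw support-feature rows (n, k)."""
        z = (np.atleast_2d(raw_support_values) - self.feature_means) / self.feature_sds
        return z @ np.asarray(self.spec.weights)


_LIGAND_SETS = {
    "ferredoxin": ("CYS", "CYS", "CYS", "CYS"),
    "rieske": ("CYS", "CYS", "HIS", "HIS"),
    "mitoneet": ("CYS", "CYS", "CYS", "HIS"),
    "rubredoxin": ("CYS", "CYS", "CYS", "CYS"),
}

_EXTRA_CODES = ("FAD", "FMN", "HEM", "SF4", "NAD")


def _random_protein_spec(p: int, rng: np.random.Generator,
                         spec: SyntheticRPSpec) -> ToyStructureSpec:
    mono = rng.random() < spec.mono_fe_fraction
    if mono:
        pclass = "rubredoxin"
    else:
        pclass = rng.choice(["ferredoxin", "ferredoxin", "rieske", "mitoneet"])
    ligands = _LIGAND_SETS[pclass]
    n_other = int(rng.integers(18, 34))
    body = tuple(rng.choice(D.AA3, size=n_other))
    shells = tuple(np.round(rng.uniform(4.2, 22.0, size=n_other), 3))
    extras = ()
    if rng.random() < 0.3:
        extras = ((str(rng.choice(_EXTRA_CODES)), float(rng.uniform(6.0, 18.0))),)
    return ToyStructureSpec(
        site_kind="mono_fe" if mono else "fe2s2",
        sequence=ligands + body, n_ligands=4, shells=shells,
        extra_cofactors=extras, resolution=float(np.round(rng.uniform(1.1, 2.9), 2)),
        seed=int(rng.integers(0, 2 ** 31 - 1)), structure_id=f"P{p:03d}"), pclass


def _mutate(spec: ToyStructureSpec, rng: np.random.Generator):
    """1-2 residue-code substitutions at fixed coordinates, off the ligands."""
    seq = list(spec.sequence)
    n_sub = int(rng.integers(1, 3))
    positions = rng.choice(np.arange(spec.n_ligands, len(seq)),
                           size=min(n_sub, len(seq) - spec.n_ligands), replace=False)
    labels = []
    for pos in positions:
        old = seq[pos]
        choices = [aa for aa in D.AA3 if aa != old]
        new = str(rng.choice(choices))
        seq[pos] = new
        labels.append(f"{old}{pos + 1}{new}")
    mutated = ToyStructureSpec(
        site_kind=spec.site_kind, sequence=tuple(seq), n_ligands=spec.n_ligands,
        shells=spec.shells, extra_cofactors=spec.extra_cofactors,
        resolution=spec.resolution, seed=spec.seed,
        structure_id=spec.structure_id)
    return mutated, "/".join(labels)


def make_synthetic_dataset(spec: SyntheticRPSpec = SyntheticRPSpec(),
                           table: D.ResiduePropertyTable = D.DEFAULT_PROPERTY_TABLE
                           ) -> SyntheticDataset:
    """Generate a cohort of toy proteins with a known linear RP model."""
    rng = np.random.default_rng(spec.seed)
    schema = D.build_schema()
    for name in spec.support:
        if name not in schema.names:
            raise ValueError(f"support feature {name!r} not in schema")
    support_idx = [schema.index(n) for n in spec.support]

    structures: dict[str, Structure] = {}
    rows = []  # (entry meta dict, raw feature vector)
    for p in range(spec.n_proteins):
        wt_spec, pclass = _random_protein_spec(p, rng, spec)
        variants = [(wt_spec, "WT")]
        for _ in range(spec.mutants_per_protein):
            variants.append(_mutate(wt_spec, rng))
        for m, (vspec, label) in enumerate(variants):
            ref = f"P{p:03d}M{m}"
            vspec = ToyStructureSpec(**{**vspec.__dict__, "structure_id": ref})
            toy = make_toy_structure(vspec)
            structures[ref] = toy.structure
            ph = float(np.round(rng.uniform(*spec.ph_range), 2))
            from .structio import detect_cluster_sites
            site = detect_cluster_sites(toy.structure)[0]
            fv = D.featurize(toy.structure, site, spec.ref_r1, spec.ref_r2, ph,
                             schema=schema, table=table)
            rows.append(({
                "entry_id": ref, "structure_ref": ref, "ph": ph,
                "protein_class": pclass, "protein_id": f"P{p:03d}",
                "mutation_label": label,
                "resolution_a": vspec.resolution,
                "is_in_silico_mutant": label != "WT",
            }, fv.values))

    raw = np.stack([v[support_idx] for _, v in rows])
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    if np.any(sds == 0):
        bad = [spec.support[i] for i in range(len(sds)) if sds[i] == 0]
        raise ValueError(f"support features constant over cohort: {bad}")
    z = (raw - means) / sds
    noise = rng.normal(0.0, spec.sigma, size=len(rows)) if spec.sigma > 0 \
        else np.zeros(len(rows))
    rp = z @ np.asarray(spec.weights) + noise

    entries = []
    for (meta, _), rp_i in zip(rows, rp):
        entries.append(DatasetEntry(
            entry_id=meta["entry_id"], structure_ref=meta["structure_ref"],
            rp_mv=float(np.clip(rp_i, -999.0, 999.0)), ph=meta["ph"],
            protein_class=meta["protein_class"], protein_id=meta["protein_id"],
            mutation_label=meta["mutation_label"],
            resolution_a=meta["resolution_a"],
            is_in_silico_mutant=meta["is_in_silico_mutant"]))
    return SyntheticDataset(entries=entries, structures=structures, spec=spec,
                            feature_means=means, feature_sds=sds, schema=schema)
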