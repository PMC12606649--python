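"""Multiscale molecular descriptors for Fe-S metal sites.

One fixed set of 66 region descriptors (10 residue-class counts plus
sum/mean/min/max of 14 numeric residue properties) is recomputed over
regions at three spatial scales:

* long range   -- the whole protein (``Protein.X``);
* medium range -- the sphere of radius r1 (8-16 A) around the cluster
  barycenter (``Bar.X``);
* short range  -- the sphere of radius r2 (3-5 A, r2 < r1) around each
  cofactor atom (``CofAtom.Y.k.X``, Y in {Fe, S}, fixed per-atom slots).

Two complementary short-scale blocks describe the residue closest in space
to each cofactor element (``NearestY.X``, 28 values) and the window of that
residue plus its two sequence neighbors (``AroundY.X``, 32 values). A
cofactor inventory (type and multiplicity of other hetero groups within r2,
within r1 and in the whole structure, plus the focal site kind) and the
measurement pH complete the vector. The default layout is a frozen,
versioned constant totalling exactly 765 features per (r1, r2).

The per-residue property table ships standard published scales (hydropathy,
volume, bulkiness, backbone flexibility, polarity, pI, net charge at
neutral pH, H-bond donor/acceptor and side-chain heteroatom counts,
molecular weight) plus a steric*flexibility composite; a drop-in
replacement table is accepted everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .structio import (ClusterSite, Residue, Structure, residues_within,
                       residues_within_any)

__all__ = [
    "ResiduePropertyTable",
    "DEFAULT_PROPERTY_TABLE",
    "FeatureSchema",
    "FeatureVector",
    "SCHEMA_VERSION",
    "R1_GRID",
    "R2_GRID",
    "build_schema",
    "build_schema_B",
    "region_descriptors",
    "long_range",
    "medium_range",
    "short_range",
    "nearest_residue_descriptors",
    "around_descriptors",
    "cofactor_inventory",
    "featurize",
    "featurize_strategy_B",
]

SCHEMA_VERSION = "1.0"

#: Radii grids used throughout (A).
R1_GRID = tuple(range(8, 17))
R2_GRID = (3, 4, 5)

#: Fixed per-atom short-range slots: capacity for up to tetra-nuclear
#: clusters; slots beyond the focal cluster's atoms are zero-filled.
N_FE_SLOTS = 4
N_S_SLOTS = 4

AA3 = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL")

# Disjoint physicochemical partition of the 20 canonical residues.
# Cys is a neutral polar residue; His groups with the basic residues.
CLASS_BASIC = {"HIS", "LYS", "ARG"}
CLASS_ACIDIC = {"ASP", "GLU"}
CLASS_POLAR_NEUTRAL = {"SER", "THR", "CYS", "ASN", "GLN", "TYR"}
CLASS_HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "GLY", "PRO"}
CLASS_AROMATIC = {"PHE", "TRP", "TYR", "HIS"}  # overlapping flag, not a partition

PROPERTY_NAMES = (
    "Hydropathy", "Volume", "Steric", "Flexibility", "StericFlex",
    "Polarity", "IsoelectricPoint", "NetCharge", "HBondDonors",
    "HBondAcceptors", "SideChainN", "SideChainO", "SideChainS", "MolWeight",
)

# Kyte-Doolittle hydropathy
_HYDROPATHY = {"ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
               "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
               "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
               "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2}
# residue volume, A^3
_VOLUME = {"ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
           "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
           "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
           "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0}
# bulkiness (steric hindrance proxy)
_STERIC = {"ALA": 11.50, "ARG": 14.28, "ASN": 12.82, "ASP": 11.68, "CYS": 13.46,
           "GLN": 14.45, "GLU": 13.57, "GLY": 3.40, "HIS": 13.69, "ILE": 21.40,
           "LEU": 21.40, "LYS": 15.71, "MET": 16.25, "PHE": 19.80, "PRO": 17.43,
           "SER": 9.47, "THR": 15.77, "TRP": 21.67, "TYR": 18.03, "VAL": 21.57}
# average backbone flexibility index
_FLEX = {"ALA": 0.357, "ARG": 0.529, "ASN": 0.463, "ASP": 0.511, "CYS": 0.346,
         "GLN": 0.493, "GLU": 0.497, "GLY": 0.544, "HIS": 0.323, "ILE": 0.462,
         "LEU": 0.365, "LYS": 0.466, "MET": 0.295, "PHE": 0.314, "PRO": 0.509,
         "SER": 0.507, "THR": 0.444, "TRP": 0.305, "TYR": 0.420, "VAL": 0.386}
# Grantham polarity
_POLARITY = {"ALA": 8.1, "ARG": 10.5, "ASN": 11.6, "ASP": 13.0, "CYS": 5.5,
             "GLN": 10.5, "GLU": 12.3, "GLY": 9.0, "HIS": 10.4, "ILE": 5.2,
             "LEU": 4.9, "LYS": 11.3, "MET": 5.7, "PHE": 5.2, "PRO": 8.0,
             "SER": 9.2, "THR": 8.6, "TRP": 5.4, "TYR": 6.2, "VAL": 5.9}
_PI = {"ALA": 6.00, "ARG": 10.76, "ASN": 5.41, "ASP": 2.77, "CYS": 5.07,
       "GLN": 5.65, "GLU": 3.22, "GLY": 5.97, "HIS": 7.59, "ILE": 6.02,
       "LEU": 5.98, "LYS": 9.74, "MET": 5.74, "PHE": 5.48, "PRO": 6.30,
       "SER": 5.68, "THR": 5.60, "TRP": 5.89, "TYR": 5.66, "VAL": 5.96}
_CHARGE = {aa: 0.0 for aa in AA3}
_CHARGE.update({"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0, "HIS": 0.1})
_HB_DON = {aa: 0.0 for aa in AA3}
_HB_DON.update({"ARG": 3, "ASN": 1, "CYS": 1, "GLN": 1, "HIS": 1, "LYS": 1,
                "SER": 1, "THR": 1, "TRP": 1, "TYR": 1})
_HB_ACC = {aa: 0.0 for aa in AA3}
_HB_ACC.update({"ASN": 1, "ASP": 2, "CYS": 1, "GLN": 1, "GLU": 2, "HIS": 1,
                "MET": 1, "SER": 1, "THR": 1, "TYR": 1})
_SC_N = {aa: 0.0 for aa in AA3}
_SC_N.update({"ARG": 3, "ASN": 1, "GLN": 1, "HIS": 2, "LYS": 1, "TRP": 1})
_SC_O = {aa: 0.0 for aa in AA3}
_SC_O.update({"ASP": 2, "GLU": 2, "ASN": 1, "GLN": 1, "SER": 1, "THR": 1, "TYR": 1})
_SC_S = {aa: 0.0 for aa in AA3}
_SC_S.update({"CYS": 1, "MET": 1})
_MW = {"ALA": 89.1, "ARG": 174.2, "ASN": 132.1, "ASP": 133.1, "CYS": 121.2,
       "GLN": 146.2, "GLU": 147.1, "GLY": 75.1, "HIS": 155.2, "ILE": 131.2,
       "LEU": 131.2, "LYS": 146.2, "MET": 149.2, "PHE": 165.2, "PRO": 115.1,
       "SER": 105.1, "THR": 119.1, "TRP": 204.2, "TYR": 181.2, "VAL": 117.1}


@dataclass(frozen=True)
class ResiduePropertyTable:
    """Per-residue class flags and numeric properties for the 20 canonical AAs."""

    properties: dict  # name -> {AA3 -> float}

    def __post_init__(self):
        for name, vals in self.properties.items():
            missing = set(AA3) - set(vals)
            if missing:
                raise ValueError(f"property {name!r}: missing residues {sorted(missing)}")

    def value(self, name: str, aa: str) -> float:
        return self.properties[name][aa]

    def matrix(self, residues: Sequence[str]) -> np.ndarray:
        """(n_residues, 14) matrix of property values in PROPERTY_NAMES order."""
        return np.array([[self.properties[p][aa] for p in PROPERTY_NAMES]
                         for aa in residues], dtype=float)


def _default_table() -> ResiduePropertyTable:
    props = {
        "Hydropathy": _HYDROPATHY, "Volume": _VOLUME, "Steric": _STERIC,
        "Flexibility": _FLEX,
        "StericFlex": {aa: _STERIC[aa] * _FLEX[aa] for aa in AA3},
        "Polarity": _POLARITY, "IsoelectricPoint": _PI, "NetCharge": _CHARGE,
        "HBondDonors": _HB_DON, "HBondAcceptors": _HB_ACC,
        "SideChainN": _SC_N, "SideChainO": _SC_O, "SideChainS": _SC_S,
        "MolWeight": _MW,
    }
    return ResiduePropertyTable(properties={k: dict(v) for k, v in props.items()})


DEFAULT_PROPERTY_TABLE = _default_table()

COUNT_NAMES = ("TotalResidues", "PolarNeutralCount", "HydrophobicCount",
               "BasicCount", "AcidicCount", "AromaticCount", "ChargedCount",
               "CysCount", "HisCount", "GlyProCount")
_AGGS = ("Sum", "Mean", "Min", "Max")
REGION_BLOCK_SIZE = len(COUNT_NAMES) + len(PROPERTY_NAMES) * len(_AGGS)  # 66

#: Hetero-group vocabulary for the cofactor inventory (unknowns -> OTHER).
INVENTORY_VOCAB = ("FES", "SF4", "F3S", "FE", "FE2", "HEM", "HEC", "FAD",
                   "FMN", "NAD", "NAP", "SAM", "MGD", "OTHER")

#: Measurement-technique categories for the optional variant schema.
TECHNIQUE_VOCAB = ("cyclic_voltammetry", "protein_film_voltammetry",
                   "redox_titration", "potentiometry", "other", "unknown")

ScaleTag = Literal["long", "medium", "short", "condition"]
RadiusDep = Literal["none", "r1", "r2"]


@dataclass(frozen=True)
class FeatureField:
    name: str
    scale_tag: ScaleTag
    radius_dep: RadiusDep
    kind: str  # "count" | "value"


@dataclass(frozen=True)
class FeatureSchema:
    fields: tuple  # tuple of FeatureField
    strategy: str  # "A" | "B"
    version: str = SCHEMA_VERSION

    def __post_init__(self):
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in schema")

    def __len__(self):
        return len(self.fields)

    @property
    def names(self) -> list:
        return [f.name for f in self.fields]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def names_by_scale(self, tags: Iterable[str]) -> list:
        tags = set(tags)
        return [f.name for f in self.fields if f.scale_tag in tags]

    def manifest(self) -> list:
        """Sidecar manifest rows: (name, scale_tag, radius_dep, kind)."""
        return [(f.name, f.scale_tag, f.radius_dep, f.kind) for f in self.fields]


@dataclass(frozen=True)
class FeatureVector:
    schema: FeatureSchema
    values: np.ndarray
    provenance: dict

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.schema),):
            raise ValueError(f"vector length {v.shape} != schema length {len(self.schema)}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature value")
        object.__setattr__(self, "values", v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.schema.index(name)])


# ---------------------------------------------------------------------------
# Schema construction

def _region_fields(prefix: str, scale: ScaleTag, radius: RadiusDep):
    fields = [FeatureField(f"{prefix}.{c}", scale, radius, "count") for c in COUNT_NAMES]
    for p in PROPERTY_NAMES:
        for agg in _AGGS:
            fields.append(FeatureField(f"{prefix}.{p}{agg}", scale, radius, "value"))
    return fields


def _nearest_fields(y: str):
    return [FeatureField(f"Nearest{y}.{p}", "short", "none", "value")
            for p in PROPERTY_NAMES]


def _around_fields(y: str):
    f = [FeatureField(f"Around{y}.{p}Sum", "short", "none", "value")
         for p in PROPERTY_NAMES]
    f += [FeatureField(f"Around{y}.CysCount", "short", "none", "count"),
          FeatureField(f"Around{y}.HisCount", "short", "none", "count")]
    return f


def _inventory_fields(scopes=(("Whole", "long", "none"),
                              ("R1", "medium", "r1"),
                              ("R2", "short", "r2"))):
    fields = []
    for code in INVENTORY_VOCAB:
        for scope, scale, dep in scopes:
            fields.append(FeatureField(f"Global.Cof.{code}.{scope}", scale, dep, "count"))
    return fields


def _cofatom_prefixes():
    return ([f"CofAtom.Fe.{k}" for k in range(1, N_FE_SLOTS + 1)]
            + [f"CofAtom.S.{k}" for k in range(1, N_S_SLOTS + 1)])


def build_schema(include_technique: bool = False) -> FeatureSchema:
    """The default strategy-A schema: exactly 765 features per (r1, r2)."""
    fields = _region_fields("Protein", "long", "none")
    fields += _region_fields("Bar", "medium", "r1")
    for prefix in _cofatom_prefixes():
        fields += _region_fields(prefix, "short", "r2")
    fields += _nearest_fields("Fe") + _nearest_fields("S")
    fields += _around_fields("Fe") + _around_fields("S")
    fields += _inventory_fields()
    fields += [FeatureField("Global.SiteKind.mono_fe", "condition", "none", "count"),
               FeatureField("Global.SiteKind.fe2s2", "condition", "none", "count")]
    fields.append(FeatureField("Global.pH", "condition", "none", "value"))
    if include_technique:
        fields += [FeatureField(f"Global.Technique.{t}", "condition", "none", "count")
                   for t in TECHNIQUE_VOCAB]
    return FeatureSchema(fields=tuple(fields), strategy="A")


def annotate_r1(name: str, r1: float) -> str:
    return f"{name}@r1={r1:g}"


def annotate_r2(name: str, r2: float) -> str:
    return f"{name}@r2={r2:g}"


def build_schema_B(r1_grid: Sequence[float] = R1_GRID,
                   r2_grid: Sequence[float] = R2_GRID) -> FeatureSchema:
    """Strategy-B schema: the deduplicated union of A-features over all radii.

    Radius-independent blocks appear once under their bare names; r1- and
    r2-dependent features appear once per grid value under annotated names.
    """
    fields = list(_region_fields("Protein", "long", "none"))
    for r1 in r1_grid:
        fields += [FeatureField(annotate_r1(f.name, r1), f.scale_tag, "r1", f.kind)
                   for f in _region_fields("Bar", "medium", "r1")]
    for r2 in r2_grid:
        for prefix in _cofatom_prefixes():
            fields += [FeatureField(annotate_r2(f.name, r2), f.scale_tag, "r2", f.kind)
                       for f in _region_fields(prefix, "short", "r2")]
    fields += _nearest_fields("Fe") + _nearest_fields("S")
    fields += _around_fields("Fe") + _around_fields("S")
    for code in INVENTORY_VOCAB:
        fields.append(FeatureField(f"Global.Cof.{code}.Whole", "long", "none", "count"))
    for r1 in r1_grid:
        for code in INVENTORY_VOCAB:
            fields.append(FeatureField(annotate_r1(f"Global.Cof.{code}.R1", r1),
                                       "medium", "r1", "count"))
    for r2 in r2_grid:
        for code in INVENTORY_VOCAB:
            fields.append(FeatureField(annotate_r2(f"Global.Cof.{code}.R2", r2),
                                       "short", "r2", "count"))
    fields += [FeatureField("Global.SiteKind.mono_fe", "condition", "none", "count"),
               FeatureField("Global.SiteKind.fe2s2", "condition", "none", "count"),
               FeatureField("Global.pH", "condition", "none", "value")]
    return FeatureSchema(fields=tuple(fields), strategy="B")


DEFAULT_SCHEMA = build_schema()


# ---------------------------------------------------------------------------
# Descriptor blocks

NonCanonicalPolicy = Literal["skip", "error"]


def _canonical_codes(residues: Iterable[Residue],
                     policy: NonCanonicalPolicy = "skip") -> list:
    codes = []
    for r in residues:
        if r.three_letter_code in AA3:
            codes.append(r.three_letter_code)
        elif policy == "error":
            raise ValueError(f"non-canonical residue {r.three_letter_code} {r.residue_key}")
        else:
            warnings.warn(f"skipping non-canonical residue {r.three_letter_code} "
                          f"{r.residue_key}", stacklevel=2)
    return codes


def region_descriptors(residues: Iterable[Residue],
                       table: ResiduePropertyTable = DEFAULT_PROPERTY_TABLE,
                       policy: NonCanonicalPolicy = "skip") -> np.ndarray:
    """The 66-descriptor block for one residue region (zeros when empty)."""
    codes = _canonical_codes(residues, policy)
    out = np.zeros(REGION_BLOCK_SIZE)
    if not codes:
        return out
    out[0] = len(codes)
    out[1] = sum(c in CLASS_POLAR_NEUTRAL for c in codes)
    out[2] = sum(c in CLASS_HYDROPHOBIC for c in codes)
    out[3] = sum(c in CLASS_BASIC for c in codes)
    out[4] = sum(c in CLASS_ACIDIC for c in codes)
    out[5] = sum(c in CLASS_AROMATIC for c in codes)
    out[6] = out[3] + out[4]
    out[7] = codes.count("CYS")
    out[8] = codes.count("HIS")
    out[9] = codes.count("GLY") + codes.count("PRO")
    m = table.matrix(codes)  # (n, 14)
    agg = np.stack([m.sum(0), m.mean(0), m.min(0), m.max(0)], axis=1)  # (14, 4)
    out[len(COUNT_NAMES):] = agg.ravel()
    return out


def long_range(structure: Structure,
               table: ResiduePropertyTable = DEFAULT_PROPERTY_TABLE,
               policy: NonCanonicalPolicy = "skip") -> np.ndarray:
    """Protein.X: the region block over all standard residues."""
    return region_descriptors(structure.residues, table, policy)


def medium_range(structure: Structure, site: ClusterSite, r1: float,
                 table: ResiduePropertyTable = DEFAULT_PROPERTY_TABLE,
                 assignment_rule: str = "any_atom",
                 policy: NonCanonicalPolicy = "skip") -> np.ndarray:
    """Bar.X: the region block within r1 of the cluster barycenter."""
    if not (R1_GRID[0] <= r1 <= R1_GRID[-1]):
        warnings.warn(f"r1={r1} outside the standard 8-16 A grid", stacklevel=2)
    region = residues_within(structure, site.barycenter, r1, assignment_rule)
    return region_descriptors(region, table, policy)


def _site_atom_slots(site: ClusterSite):
    """(element, coords) per fixed slot; None for empty slots."""
    fe = [c for e, c in site.cofactor_atoms if e == "FE"]
    s = [c for e, c in site.cofactor_atoms if e == "S"]
    slots = [fe[k] if k < len(fe) else None for k in range(N_FE_SLOTS)]
    slots += [s[k] if k < len(s) else None for k in range(N_S_SLOTS)]
    return slots


def short_range(structure: Structure, site: ClusterSite, r2: float,
                table: ResiduePropertyTable = DEFAULT_PROPERTY_TABLE,
                assignment_rule: str = "any_atom",
                policy: NonCanonicalPolicy = "skip") -> np.ndarray:
    """CofAtom.Y.k.X: one region block per cofactor-atom slot within r2.

    Empty slots (e.g. all S slots of a mononuclear site) are zero-filled.
    """
    if not (R2_GRID[0] <= r2 <= R2_GRID[-1]):
        warnings.warn(f"r2={r2} outside the standard 3-5 A grid", stacklevel=2)
    blocks = []
    for coords in _site_atom_slots(site):
        if coords is None:
            blocks.append(np.zeros(REGION_BLOCK_SIZE))
        else:
            region = residues_within(structure, coords, r2, assignment_rule)
            blocks.append(region_descriptors(region, table, policy))
    return np.concatenate(blocks)


def _nearest_residue(structure: Structure, coords_list) -> Residue | None:
    """Residue with minimum atom-atom distance to any of the given points.

    Ties break by (chain id, residue number) ascending.
    """
    if len(coords_list) == 0:
        return None
    pts = np.stack(coords_list)
    best = None
    for res in structure.residues:
        d = float(np.min(np.linalg.norm(
            res.coord_array[:, None, :] - pts[None, :, :], axis=2)))
        key = (d, res.residue_key[0], res.residue_key[1])
        if best is None or key < best[0]:
            best = (key, res)
    return best[1] if best else None


def nearest_residue_descriptors(structure: Structure, site: ClusterSite,
                                table: ResiduePropertyTable = DEFAULT_PROPERTY_TABLE
                                ) -> np.ndarray:
    """NearestY.X: the 14 property values of the residue closest to each element."""
    out = []
    for coords in (site.fe_coords(), site.s_coords()):
        res = _nearest_residue(structure, coords)
        if res is None or res.three_letter_code not in AA3:
            out.append(np.zeros(len(PROPERTY_NAMES)))
        else:
            out.append(table.matrix([res.three_letter_code])[0])
    return np.concatenate(out)


def _sequence_window(structure: Structure, res: Residue) -> list:
    """The residue and its i-1 / i+1 sequence neighbors in the same chain."""
    chain = [r for r in structure.residues if r.residue_key[0] == res.residue_key[0]]
    i = next(k for k, r in enumerate(chain) if r.residue_key == res.residue_key)
    return chain[max(0, i - 1):i + 2]


def around_descriptors(structure: Structure, site: ClusterSite,
                       table: ResiduePropertyTable = DEFAULT_PROPERTY_TABLE
                       ) -> np.ndarray:
    """AroundY.X: property sums plus Cys/His counts over the nearest residue
    and its two sequence-adjacent neighbors (termini keep the one existing
    neighbor)."""
    out = []
    for coords in (site.fe_coords(), site.s_coords()):
        res = _nearest_residue(structure, coords)
        if res is None:
            out.append(np.zeros(len(PROPERTY_NAMES) + 2))
            continue
        window = _sequence_window(structure, res)
        codes = [r.three_letter_code for r in window if r.three_letter_code in AA3]
        block = np.zeros(len(PROPERTY_NAMES) + 2)
        if codes:
            block[:len(PROPERTY_NAMES)] = table.matrix(codes).sum(0)
            block[len(PROPERTY_NAMES)] = codes.count("CYS")
            block[len(PROPERTY_NAMES) + 1] = codes.count("HIS")
        out.append(block)
    return np.concatenate(out)


def _group_barycenter(group: Residue) -> np.ndarray:
    return np.mean(group.coord_array, axis=0)


def cofactor_inventory(structure: Structure, site: ClusterSite,
                       r1: float, r2: float) -> np.ndarray:
    """Counts of non-focal cofactor groups per vocabulary code and scope.

    Scope membership is decided by the group barycenter's distance to the
    focal cluster barycenter (whole structure / within r1 / within r2).
    Codes outside the vocabulary bucket into OTHER.
    """
    counts = {code: np.zeros(3) for code in INVENTORY_VOCAB}
    for group in structure.hetero_groups:
        if group.residue_key == site.residue_key:
            continue
        code = group.three_letter_code if group.three_letter_code in INVENTORY_VOCAB \
            else "OTHER"
        d = float(np.linalg.norm(_group_barycenter(group) - site.barycenter))
        counts[code][0] += 1
        if d <= r1:
            counts[code][1] += 1
        if d <= r2:
            counts[code][2] += 1
    return np.concatenate([counts[code] for code in INVENTORY_VOCAB])


def _site_kind_flags(site: ClusterSite) -> np.ndarray:
    return np.array([float(site.site_kind == "mono_fe"),
                     float(site.site_kind == "fe2s2")])


def _technique_onehot(technique: str | None) -> np.ndarray:
    t = technique if technique in TECHNIQUE_VOCAB else ("unknown" if technique in
                                                        (None, "") else "other")
    return np.array([float(t == cat) for cat in TECHNIQUE_VOCAB])


def featurize(structure: Structure, site: ClusterSite, r1: float, r2: float,
              conditions: dict | float,
              schema: FeatureSchema | None = None,
              table: ResiduePropertyTable = DEFAULT_PROPERTY_TABLE,
              assignment_rule: str = "any_atom",
              policy: NonCanonicalPolicy = "skip") -> FeatureVector:
    """Assemble one strategy-A feature vector for a single (r1, r2).

    ``conditions`` is the measurement pH, or a dict with keys ``ph`` and
    (variant schema only) ``technique``.
    """
    if isinstance(conditions, dict):
        ph = float(conditions["ph"])
        technique = conditions.get("technique")
    else:
        ph, technique = float(conditions), None
    if r2 >= r1:
        raise ValueError(f"r2 ({r2}) must be smaller than r1 ({r1})")
    if not (0.0 <= ph <= 14.0):
        raise ValueError(f"pH {ph} outside [0, 14]")
    schema = schema or DEFAULT_SCHEMA
    parts = [
        long_range(structure, table, policy),
        medium_range(structure, site, r1, table, assignment_rule, policy),
        short_range(structure, site, r2, table, assignment_rule, policy),
        nearest_residue_descriptors(structure, site, table),
        around_descriptors(structure, site, table),
        cofactor_inventory(structure, site, r1, r2),
        _site_kind_flags(site),
        np.array([ph]),
    ]
    if any(f.name.startswith("Global.Technique.") for f in schema.fields):
        parts.append(_technique_onehot(technique))
    values = np.concatenate(parts)
    return FeatureVector(schema=schema, values=values,
                         provenance={"structure_id": structure.id,
                                     "site": site.residue_key,
                                     "r1": r1, "r2": r2, "ph": ph})


def featurize_strategy_B(structure: Structure, site: ClusterSite,
                         conditions: dict | float,
                         schema: FeatureSchema | None = None,
                         r1_grid: Sequence[float] = R1_GRID,
                         r2_grid: Sequence[float] = R2_GRID,
                         table: ResiduePropertyTable = DEFAULT_PROPERTY_TABLE,
                         assignment_rule: str = "any_atom",
                         policy: NonCanonicalPolicy = "skip") -> FeatureVector:
    """Assemble the strategy-B vector: unique features across all radii pairs."""
    ph = float(conditions["ph"]) if isinstance(conditions, dict) else float(conditions)
    if not (0.0 <= ph <= 14.0):
        raise ValueError(f"pH {ph} outside [0, 14]")
    schema = schema or build_schema_B(r1_grid, r2_grid)
    parts = [long_range(structure, table, policy)]
    for r1 in r1_grid:
        parts.append(medium_range(structure, site, r1, table, assignment_rule, policy))
    for r2 in r2_grid:
        parts.append(short_range(structure, site, r2, table, assignment_rule, policy))
    parts.append(nearest_residue_descriptors(structure, site, table))
    parts.append(around_descriptors(structure, site, table))
    inv_whole = None
    inv_r1, inv_r2 = [], []
    for r1 in r1_grid:
        inv = cofactor_inventory(structure, site, r1, min(r2_grid)).reshape(-1, 3)
        inv_whole = inv[:, 0]
        inv_r1.append(inv[:, 1])
    for r2 in r2_grid:
        inv = cofactor_inventory(structure, site, max(r1_grid), r2).reshape(-1, 3)
        inv_r2.append(inv[:, 2])
    parts.append(inv_whole)
    parts.extend(inv_r1)
    parts.extend(inv_r2)
    parts.append(_site_kind_flags(site))
    parts.append(np.array([ph]))
    values = np.concatenate(parts)
    return FeatureVector(schema=schema, values=values,
                         provenance={"structure_id": structure.id,
                                     "site": site.residue_key,
                                     "r1": tuple(r1_grid), "r2": tuple(r2_grid),
                                     "ph": ph})
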