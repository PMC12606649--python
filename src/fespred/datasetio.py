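"""Curated-table loading and design-matrix assembly.

The experimental table is delimited text (comma or tab, autodetected) with
one row per measurement: structure reference, optional site selector,
reduction potential (mV), pH, protein class, optional technique and
resolution, mutation label, and a parent-protein id used for
leakage-aware grouping. Column names are matched through a small alias
table so common spellings all work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import descriptors as D
from .structio import Structure, detect_cluster_sites, read_pdb

__all__ = [
    "DatasetEntry",
    "DesignMatrix",
    "FeaturizerConfig",
    "DatasetValidationError",
    "load_dataset",
    "build_design_matrix",
    "write_dataset",
]

log = logging.getLogger(__name__)

PROTEIN_CLASSES = ("ferredoxin", "mitoneet", "rieske", "rubredoxin", "other")

RP_RANGE = (-1000.0, 1000.0)

_COLUMN_ALIASES = {
    "entry_id": {"entry_id", "id", "entry"},
    "structure_ref": {"structure_ref", "structure", "pdb", "pdb_id", "file", "path"},
    "site_chain": {"site_chain", "chain"},
    "site_resnum": {"site_resnum", "site_residue", "resnum", "cluster_resnum"},
    "rp_mv": {"rp_mv", "rp", "em_mv", "potential_mv", "redox_potential_mv"},
    "ph": {"ph"},
    "protein_class": {"protein_class", "class", "type", "family"},
    "technique": {"technique", "method"},
    "resolution_a": {"resolution_a", "resolution"},
    "mutation_label": {"mutation_label", "mutation", "mutant"},
    "is_in_silico_mutant": {"is_in_silico_mutant", "in_silico"},
    "protein_id": {"protein_id", "protein", "parent", "parent_protein"},
}


class DatasetValidationError(ValueError):
    """Carries the itemized list of row-level validation problems."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("dataset validation failed:\n  " + "\n  ".join(self.problems))


@dataclass(frozen=True)
class DatasetEntry:
    entry_id: str
    structure_ref: str
    rp_mv: float
    ph: float
    protein_class: str
    protein_id: str
    site_selector: tuple | None = None  # (chain, residue number)
    technique: str | None = None
    resolution_a: float | None = None
    mutation_label: str = "WT"
    is_in_silico_mutant: bool = False

    @property
    def is_wild_type(self) -> bool:
        return self.mutation_label.upper() == "WT"


@dataclass
class DesignMatrix:
    """Feature matrix aligned with targets, groups and entry metadata."""

    X: pd.DataFrame  # rows indexed by entry_id, columns = schema names
    y: pd.Series  # RP, mV
    groups: pd.Series  # parent protein id per entry
    schema: D.FeatureSchema
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.X.isna().any().any():
            raise ValueError("design matrix contains undefined cells")
        if not (self.X.index.equals(self.y.index) and self.X.index.equals(self.groups.index)):
            raise ValueError("X / y / groups indices are not aligned")

    def __len__(self):
        return len(self.X)

    def subset_columns(self, names: Sequence[str]) -> "DesignMatrix":
        return DesignMatrix(X=self.X[list(names)], y=self.y, groups=self.groups,
                            schema=self.schema, meta=self.meta)

    def subset_rows(self, entry_ids: Sequence[str]) -> "DesignMatrix":
        ids = list(entry_ids)
        return DesignMatrix(X=self.X.loc[ids], y=self.y.loc[ids],
                            groups=self.groups.loc[ids], schema=self.schema,
                            meta=self.meta.loc[ids] if len(self.meta) else self.meta)


@dataclass(frozen=True)
class FeaturizerConfig:
    strategy: str = "A"  # "A" | "B"
    r1: float = 11.0
    r2: float = 4.0
    r1_grid: tuple = D.R1_GRID
    r2_grid: tuple = D.R2_GRID
    include_technique: bool = False
    assignment_rule: str = "any_atom"

    def __post_init__(self):
        if self.strategy not in ("A", "B"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "A" and self.r2 >= self.r1:
            raise ValueError("strategy A requires r2 < r1")


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    lower = {c: c.strip().lower() for c in df.columns}
    rename = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for col, low in lower.items():
            if low in aliases:
                rename[col] = canonical
    return df.rename(columns=rename)


def load_dataset(path: str | Path) -> list:
    """Load and validate the curated table; returns a list of DatasetEntry."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df = _normalize_columns(df)

    problems = []
    required = ["entry_id", "structure_ref", "rp_mv", "ph", "protein_class"]
    for col in required:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        raise DatasetValidationError(problems)

    entries = []
    seen_ids = set()
    for i, row in df.iterrows():
        rowname = f"row {i + 2} ({row.get('entry_id', '?')})"  # +2: header + 1-based
        eid = str(row["entry_id"])
        if eid in seen_ids:
            problems.append(f"{rowname}: duplicate entry_id")
            continue
        seen_ids.add(eid)
        try:
            rp = float(row["rp_mv"])
            ph = float(row["ph"])
        except (TypeError, ValueError):
            problems.append(f"{rowname}: non-numeric RP or pH")
            continue
        if not (RP_RANGE[0] <= rp <= RP_RANGE[1]) or not np.isfinite(rp):
            problems.append(f"{rowname}: RP {rp} mV outside {RP_RANGE}")
            continue
        if not (0.0 <= ph <= 14.0):
            problems.append(f"{rowname}: pH {ph} outside [0, 14]")
            continue
        pclass = str(row["protein_class"]).strip().lower().replace("-", "")
        if pclass not in PROTEIN_CLASSES:
            problems.append(f"{rowname}: unknown protein class {row['protein_class']!r}")
            continue
        selector = None
        if "site_chain" in df.columns and pd.notna(row.get("site_chain")) \
                and pd.notna(row.get("site_resnum")):
            selector = (str(row["site_chain"]), int(row["site_resnum"]))
        resolution = None
        if "resolution_a" in df.columns and pd.notna(row.get("resolution_a")):
            resolution = float(row["resolution_a"])
        technique = None
        if "technique" in df.columns and pd.notna(row.get("technique")):
            technique = str(row["technique"])
        mutation = str(row.get("mutation_label", "WT")) \
            if pd.notna(row.get("mutation_label", "WT")) else "WT"
        protein_id = str(row["protein_id"]) if "protein_id" in df.columns \
            and pd.notna(row.get("protein_id")) else str(row["structure_ref"])
        in_silico = bool(row.get("is_in_silico_mutant", False)) \
            if pd.notna(row.get("is_in_silico_mutant", False)) else False
        entries.append(DatasetEntry(
            entry_id=eid, structure_ref=str(row["structure_ref"]), rp_mv=rp, ph=ph,
            protein_class=pclass, protein_id=protein_id, site_selector=selector,
            technique=technique, resolution_a=resolution, mutation_label=mutation,
            is_in_silico_mutant=in_silico))

    if problems:
        raise DatasetValidationError(problems)

    by_class = pd.Series([e.protein_class for e in entries]).value_counts().to_dict()
    rps = [e.rp_mv for e in entries]
    log.info("loaded %d entries (%s); RP range [%.0f, %.0f] mV",
             len(entries), by_class, min(rps), max(rps))
    return entries


def write_dataset(entries: Sequence[DatasetEntry], path: str | Path) -> None:
    """Write entries back out in the canonical curated-table dialect (CSV)."""
    rows = []
    for e in entries:
        rows.append({
            "entry_id": e.entry_id, "structure_ref": e.structure_ref,
            "site_chain": e.site_selector[0] if e.site_selector else "",
            "site_resnum": e.site_selector[1] if e.site_selector else "",
            "rp_mv": e.rp_mv, "ph": e.ph, "protein_class": e.protein_class,
            "technique": e.technique or "", "resolution_a": e.resolution_a,
            "mutation_label": e.mutation_label,
            "is_in_silico_mutant": e.is_in_silico_mutant,
            "protein_id": e.protein_id,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def _resolve_structures(entries, structures, structure_dir):
    resolved, missing = {}, []
    for e in entries:
        ref = e.structure_ref
        if ref in resolved:
            continue
        if structures is not None and ref in structures:
            resolved[ref] = structures[ref]
            continue
        candidates = []
        if structure_dir is not None:
            candidates = [Path(structure_dir) / ref, Path(structure_dir) / f"{ref}.pdb"]
        candidates.append(Path(ref))
        hit = next((c for c in candidates if c.exists()), None)
        if hit is None:
            missing.append(ref)
        else:
            resolved[ref] = read_pdb(hit, structure_id=ref)
    if missing:
        raise FileNotFoundError(
            "unresolvable structure references: " + ", ".join(sorted(set(missing))))
    return resolved


def build_design_matrix(entries: Sequence[DatasetEntry],
                        config: FeaturizerConfig = FeaturizerConfig(),
                        structures: Mapping[str, Structure] | None = None,
                        structure_dir: str | Path | None = None,
                        table: D.ResiduePropertyTable = D.DEFAULT_PROPERTY_TABLE,
                        policy: str = "skip") -> DesignMatrix:
    """Featurize every entry and align features, targets, groups and metadata."""
    resolved = _resolve_structures(entries, structures, structure_dir)
    if config.strategy == "A":
        schema = D.build_schema(include_technique=config.include_technique)
    else:
        schema = D.build_schema_B(config.r1_grid, config.r2_grid)

    site_cache: dict = {}
    rows, ids = [], []
    for e in entries:
        structure = resolved[e.structure_ref]
        key = (e.structure_ref, e.site_selector)
        if key not in site_cache:
            site_cache[key] = detect_cluster_sites(structure, e.site_selector)[0]
        site = site_cache[key]
        conditions = {"ph": e.ph, "technique": e.technique}
        try:
            if config.strategy == "A":
                fv = D.featurize(structure, site, config.r1, config.r2, conditions,
                                 schema=schema, table=table,
                                 assignment_rule=config.assignment_rule, policy=policy)
            else:
                fv = D.featurize_strategy_B(structure, site, conditions, schema=schema,
                                            r1_grid=config.r1_grid,
                                            r2_grid=config.r2_grid, table=table,
                                            assignment_rule=config.assignment_rule,
                                            policy=policy)
        except Exception as exc:
            raise RuntimeError(f"featurization failed for entry {e.entry_id}: {exc}") from exc
        rows.append(fv.values)
        ids.append(e.entry_id)

    X = pd.DataFrame(np.stack(rows), index=ids, columns=schema.names)
    y = pd.Series([e.rp_mv for e in entries], index=ids, name="rp_mv")
    groups = pd.Series([e.protein_id for e in entries], index=ids, name="protein_id")
    meta = pd.DataFrame({
        "protein_class": [e.protein_class for e in entries],
        "mutation_label": [e.mutation_label for e in entries],
        "resolution_a": [e.resolution_a for e in entries],
        "ph": [e.ph for e in entries],
    }, index=ids)
    return DesignMatrix(X=X, y=y, groups=groups, schema=schema, meta=meta)


def write_matrix(matrix: DesignMatrix, prefix: str | Path) -> None:
    """Write the feature matrix (CSV, header = schema names) and its manifest."""
    prefix = Path(prefix)
    out = matrix.X.copy()
    out.insert(0, "rp_mv", matrix.y)
    out.insert(1, "protein_id", matrix.groups)
    out.to_csv(prefix.with_suffix(".features.csv"))
    manifest = pd.DataFrame(matrix.schema.manifest(),
                            columns=["name", "scale_tag", "radius_dep", "kind"])
    manifest.to_csv(prefix.with_suffix(".schema.csv"), index=False)
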