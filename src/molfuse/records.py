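"""Dataset ingestion, SMILES canonicalization, cleaning and 3D conformer embedding.

Molecules enter the pipeline as SMILES rows in a CSV table (plus, optionally,
SDF files that already carry coordinates).  Every downstream stage works on
:class:`MoleculeRecord` objects: a parsed, canonicalized molecule with its
per-task labels and — once :func:`embed_conformer` has run — one
force-field-optimized 3D conformer over the heavy atoms.

Hydrogens are implicit throughout: they are folded into atom features, never
graph nodes, so ``N`` below always means the heavy-atom count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

CLASSIFICATION = "classification"
REGRESSION = "regression"
TASK_TYPES = (CLASSIFICATION, REGRESSION)


@dataclass
class MoleculeRecord:
    """One molecule: raw and canonical SMILES, labels, optional 3D coordinates.

    ``targets`` holds one float per task; missing labels are ``nan``.
    ``coords`` is an ``N_heavy x 3`` array in Angstroms, present only after
    conformer embedding (or SDF input).  ``used_2d_fallback`` flags records
    whose distance-geometry embedding failed and fell back to a planar layout.
    """

    raw_smiles: str
    canonical_smiles: Optional[str]
    targets: np.ndarray
    coords: Optional[np.ndarray] = None
    valid: bool = True
    used_2d_fallback: bool = False

    def mol(self) -> Chem.Mol:
        """Return the parsed RDKit molecule (heavy atoms only)."""
        if not self.valid:
            raise ValueError(f"record {self.raw_smiles!r} is not a valid molecule")
        return Chem.MolFromSmiles(self.canonical_smiles)

    @property
    def n_heavy(self) -> int:
        return self.mol().GetNumAtoms()


@dataclass
class DatasetTable:
    """Ordered molecule records plus task metadata (uniform task type)."""

    records: List[MoleculeRecord]
    task_names: List[str]
    task_type: str

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"task_type must be one of {TASK_TYPES}, got {self.task_type!r}")
        for rec in self.records:
            if len(rec.targets) != len(self.task_names):
                raise ValueError("record target length does not match task_names")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    def targets_matrix(self) -> np.ndarray:
        """All labels as an ``n_molecules x n_tasks`` float array (nan = missing)."""
        if not self.records:
            return np.empty((0, self.n_tasks))
        return np.stack([r.targets for r in self.records])

    def subset(self, indices: Sequence[int]) -> "DatasetTable":
        return DatasetTable([self.records[i] for i in indices], list(self.task_names), self.task_type)


@dataclass
class CleaningReport:
    n_input: int
    n_duplicates_removed: int
    n_invalid_removed: int
    n_output: int

    def __post_init__(self) -> None:
        assert self.n_output == self.n_input - self.n_duplicates_removed - self.n_invalid_removed

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def canonicalize(smiles: str) -> Optional[str]:
    """Canonical SMILES via RDKit, or None if the string does not parse to a
    molecule with at least one heavy atom."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def make_record(smiles: str, targets: Sequence[float]) -> MoleculeRecord:
    canonical = canonicalize(smiles)
    return MoleculeRecord(
        raw_smiles=smiles,
        canonical_smiles=canonical,
        targets=np.asarray(targets, dtype=float),
        valid=canonical is not None,
    )


def read_dataset(
    path: str,
    smiles_column: str,
    target_columns: Sequence[str],
    task_type: str,
) -> DatasetTable:
    """Read a CSV into a :class:`DatasetTable`, one record per row in file order.

    Unparseable target cells (empty strings, text) become missing labels; the
    record itself is retained.  Missing columns raise ``KeyError`` naming the
    offender.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in [smiles_column, *target_columns]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    records = []
    for _, row in df.iterrows():
        targets = [pd.to_numeric(row[c], errors="coerce") for c in target_columns]
        records.append(make_record(row[smiles_column], targets))
    return DatasetTable(records, list(target_columns), task_type)


def read_sdf(path: str, target_props: Sequence[str], task_type: str) -> DatasetTable:
    """Read an SDF file; 3D coordinates in the file are kept, so conformer
    embedding can be skipped for these records."""
    records = []
    supplier = Chem.SDMolSupplier(path, removeHs=True)
    for mol in supplier:
        if mol is None:
            records.append(MoleculeRecord("<unparseable sdf entry>", None, np.full(len(target_props), np.nan), valid=False))
            continue
        targets = []
        for prop in target_props:
            try:
                targets.append(float(mol.GetProp(prop)))
            except (KeyError, ValueError):
                targets.append(np.nan)
        coords = None
        if mol.GetNumConformers() > 0:
            coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        records.append(
            MoleculeRecord(
                raw_smiles=Chem.MolToSmiles(mol),
                canonical_smiles=Chem.MolToSmiles(mol),
                targets=np.asarray(targets, dtype=float),
                coords=coords,
            )
        )
    return DatasetTable(records, list(target_props), task_type)


def clean_dataset(data: DatasetTable) -> Tuple[DatasetTable, CleaningReport]:
    """Drop invalid records and canonical-SMILES duplicates (first kept).

    Conflicting labels within a duplicate group are logged, never merged.
    Idempotent: cleaning a clean table is the identity.
    """
    seen: dict = {}
    kept: List[MoleculeRecord] = []
    n_dup = 0
    n_invalid = 0
    for rec in data.records:
        if not rec.valid:
            n_invalid += 1
            continue
        if rec.canonical_smiles in seen:
            n_dup += 1
            first = seen[rec.canonical_smiles]
            both = ~(np.isnan(first.targets) | np.isnan(rec.targets))
            if np.any(first.targets[both] != rec.targets[both]):
                logger.warning(
                    "duplicate %s has conflicting labels (%s vs %s); keeping first occurrence",
                    rec.canonical_smiles, first.targets, rec.targets,
                )
            continue
        seen[rec.canonical_smiles] = rec
        kept.append(rec)
    report = CleaningReport(len(data.records), n_dup, n_invalid, len(kept))
    return DatasetTable(kept, list(data.task_names), data.task_type), report


def embed_conformer(
    record: MoleculeRecord,
    seed: int,
    force_field: str = "uff",
) -> MoleculeRecord:
    """Attach one 3D conformer: distance-geometry embedding followed by
    force-field optimization (UFF by default, MMFF94 via ``force_field="mmff"``).

    Deterministic for a fixed seed.  If 3D embedding fails, falls back to the
    planar 2D layout with z = 0 and flags the record rather than dropping it.
    Embedding runs with explicit hydrogens for geometry quality; only the
    heavy-atom coordinates are retained.
    """
    if not record.valid:
        raise ValueError(f"cannot embed invalid record {record.raw_smiles!r}")
    mol = record.mol()
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    conf_id = AllChem.EmbedMolecule(molh, params)
    fallback = False
    if conf_id >= 0:
        try:
            if force_field == "mmff":
                AllChem.MMFFOptimizeMolecule(molh)
            else:
                AllChem.UFFOptimizeMolecule(molh)
        except Exception:  # optimization failure: keep the raw DG geometry
            pass
        molh = Chem.RemoveHs(molh)
        coords = np.array(molh.GetConformer().GetPositions(), dtype=float)
    else:
        AllChem.Compute2DCoords(mol)
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        coords[:, 2] = 0.0
        fallback = True
    assert coords.shape == (mol.GetNumAtoms(), 3)
    return replace(record, coords=coords, used_2d_fallback=fallback)


def embed_dataset(data: DatasetTable, seed: int, force_field: str = "uff") -> DatasetTable:
    """Embed every record lacking coordinates; records with coordinates
    (e.g. from SDF input) pass through untouched."""
    out = []
    for i, rec in enumerate(data.records):
        if rec.coords is None:
            # per-record seed keeps results independent of dataset order
            rec = embed_conformer(rec, seed=(int(seed) * 1000003 + i) & 0x7FFFFFFF, force_field=force_field)
        out.append(rec)
    return DatasetTable(out, list(data.task_names), data.task_type)
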