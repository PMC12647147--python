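"""Molecular fingerprint families and concatenated panels.

Eight candidate families are supported — ECFP (Morgan), the RDKit path
fingerprint, MACCS keys, EState indices, ErG pharmacophore, atom pairs,
topological torsions and Avalon — and any 1–3-way combination of them can be
concatenated into a :class:`FingerprintPanel` that feeds the fingerprint FNN
channel.  Task-dependent default panels:

* classification: ``ErG + ECFP + RDKitFP``
* regression:     ``EState + ErG + ECFP``

All fingerprints are computed on the canonical molecule, so two SMILES
spellings of the same structure always yield identical vectors.  ErG and
EState are real-valued; real-valued columns are expected to be z-scored with
training-set statistics before entering the FNN (see ``panel_real_mask``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator, rdReducedGraphs
from rdkit.Chem.EState import Fingerprinter as _EStateFP

from .records import CLASSIFICATION, REGRESSION, DatasetTable, MoleculeRecord


@dataclass(frozen=True)
class FingerprintFamily:
    name: str
    width: int
    value_kind: str  # binary | real


_ECFP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
_RDKIT_GEN = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
_ATOMPAIR_GEN = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=2048)
_TORSION_GEN = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=2048)


def _bits(fp) -> np.ndarray:
    return np.array(fp, dtype=float)


_COMPUTE = {
    "ECFP": lambda mol: _bits(_ECFP_GEN.GetFingerprint(mol)),
    "RDKitFP": lambda mol: _bits(_RDKIT_GEN.GetFingerprint(mol)),
    "MACCS": lambda mol: _bits(MACCSkeys.GenMACCSKeys(mol)),
    "EState": lambda mol: np.asarray(_EStateFP.FingerprintMol(mol)[1], dtype=float),
    "ErG": lambda mol: np.asarray(rdReducedGraphs.GetErGFingerprint(mol), dtype=float),
    "AtomPair": lambda mol: _bits(_ATOMPAIR_GEN.GetFingerprint(mol)),
    "TopologicalTorsion": lambda mol: _bits(_TORSION_GEN.GetFingerprint(mol)),
    "Avalon": lambda mol: _bits(pyAvalonTools.GetAvalonFP(mol, nBits=512)),
}

FAMILIES = {
    "ECFP": FingerprintFamily("ECFP", 2048, "binary"),
    "RDKitFP": FingerprintFamily("RDKitFP", 2048, "binary"),
    "MACCS": FingerprintFamily("MACCS", 167, "binary"),
    "EState": FingerprintFamily("EState", 79, "real"),
    "ErG": FingerprintFamily("ErG", 315, "real"),
    "AtomPair": FingerprintFamily("AtomPair", 2048, "binary"),
    "TopologicalTorsion": FingerprintFamily("TopologicalTorsion", 2048, "binary"),
    "Avalon": FingerprintFamily("Avalon", 512, "binary"),
}

FAMILY_NAMES = tuple(FAMILIES)


@dataclass
class FingerprintPanel:
    families: List[FingerprintFamily]
    vector: np.ndarray


def _resolve(family) -> FingerprintFamily:
    if isinstance(family, FingerprintFamily):
        family = family.name
    try:
        return FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown fingerprint family {family!r}; choose from {FAMILY_NAMES}") from None


def compute_fingerprint(record: MoleculeRecord, family) -> np.ndarray:
    """One family's vector for one molecule (binary families emit 0/1)."""
    if not record.valid:
        raise ValueError(f"cannot fingerprint invalid record {record.raw_smiles!r}")
    fam = _resolve(family)
    vec = _COMPUTE[fam.name](record.mol())
    assert vec.shape == (fam.width,)
    return vec


def fingerprint_panel(record: MoleculeRecord, families: Sequence) -> FingerprintPanel:
    """Concatenate the named families, in order, into one panel vector."""
    fams = [_resolve(f) for f in families]
    if not fams:
        raise ValueError("families must be nonempty")
    names = [f.name for f in fams]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate fingerprint families in {names}")
    vector = np.concatenate([compute_fingerprint(record, f) for f in fams])
    return FingerprintPanel(fams, vector)


def panel_width(families: Iterable) -> int:
    return sum(_resolve(f).width for f in families)


def panel_real_mask(families: Sequence) -> np.ndarray:
    """Boolean mask over panel columns: True where the column is real-valued
    (and should be z-scored with training-set statistics)."""
    parts = [np.full(_resolve(f).width, _resolve(f).value_kind == "real") for f in families]
    return np.concatenate(parts)


def default_families(task_type: str) -> List[str]:
    """The task-dependent default panels."""
    if task_type == CLASSIFICATION:
        return ["ErG", "ECFP", "RDKitFP"]
    if task_type == REGRESSION:
        return ["EState", "ErG", "ECFP"]
    raise ValueError(f"unknown task_type {task_type!r}")


def panel_matrix(data: DatasetTable, families: Sequence) -> np.ndarray:
    """Panel vectors for a whole dataset, one molecule per row."""
    return np.stack([fingerprint_panel(r, families).vector for r in data.records])


def export_panels_csv(data: DatasetTable, families: Sequence, path: str) -> None:
    """Dump panels as CSV (smiles + one column per panel position)."""
    import pandas as pd

    mat = panel_matrix(data, families)
    cols = []
    for f in families:
        fam = _resolve(f)
        cols.extend(f"{fam.name}_{i}" for i in range(fam.width))
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "smiles", [r.canonical_smiles for r in data.records])
    df.to_csv(path, index=False)
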