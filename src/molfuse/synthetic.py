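"""Deterministic synthetic molecule and label generation.

Every experiment in the package can run without downloads: molecules are
assembled from a curated pool of drug-like fragments joined by single bonds
through a seeded grammar, which guarantees chemical validity without
rejection sampling, and labels are synthesized under one of three modes:

* ``motif_classification`` — label 1 iff the molecule matches a SMARTS motif
  (default: a benzene ring), optionally flipped with probability
  ``noise_rate``;
* ``additive_regression`` — sum of a fixed per-element contribution table
  over heavy atoms, plus Gaussian noise (``noise_sd``);
* ``geometry_regression`` — radius of gyration of the embedded 3D conformer
  plus Gaussian noise.  Only the 3D geometry carries this signal, which is
  what makes the equivariant channel's contribution measurable.

These fixtures emulate the label structure of property-prediction
benchmarks (substructure-driven activity, additive physicochemical
properties, conformation-dependent properties) at desk scale; they do not
attempt to match real ADME/toxicity label distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol

from .records import CLASSIFICATION, REGRESSION, DatasetTable, embed_dataset, make_record

# complete, individually valid fragments; molecules are 1-3 of these joined
# by single bonds at atoms with free valence
FRAGMENT_POOL = (
    "c1ccccc1",      # benzene
    "c1ccc(C)cc1",   # toluene
    "c1ccncc1",      # pyridine
    "c1ccsc1",       # thiophene
    "c1cc[nH]c1",    # pyrrole
    "C1CCCCC1",      # cyclohexane
    "C1CCNCC1",      # piperidine
    "C1CCOC1",       # tetrahydrofuran
    "CCO",           # ethanol
    "CCN",           # ethylamine
    "CC(C)C",        # isobutane
    "CC(=O)O",       # acetic acid
    "CC(=O)N",       # acetamide
    "COC",           # dimethyl ether
    "CSC",           # dimethyl sulfide
    "CC#N",          # acetonitrile
    "CCF",           # fluoroethane
    "CCCl",          # chloroethane
    "CCBr",          # bromoethane
    "C=CC",          # propene
)

# fixed per-element contributions (arbitrary units) for additive_regression
ELEMENT_CONTRIBUTION = {6: 0.5, 7: -1.2, 8: -0.9, 16: 0.3, 9: -0.4, 17: 0.8, 35: 1.1, 15: 0.2}


@dataclass
class FixtureSpec:
    n_molecules: int = 100
    seed: int = 0
    label_mode: str = "motif_classification"
    motif: str = "c1ccccc1"
    noise_rate: float = 0.0
    noise_sd: float = 0.0
    max_fragments: int = 3

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0,1]")
        if self.label_mode not in ("motif_classification", "additive_regression", "geometry_regression"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")

    @property
    def task_type(self) -> str:
        return CLASSIFICATION if self.label_mode == "motif_classification" else REGRESSION


def _free_valence_atoms(mol: Chem.Mol) -> List[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetNumImplicitHs() > 0]


def _join(a: Chem.Mol, b: Chem.Mol, rng: np.random.Generator) -> Optional[Chem.Mol]:
    """Join two fragments with a single bond at seeded attachment points."""
    ai = _free_valence_atoms(a)
    bi = _free_valence_atoms(b)
    if not ai or not bi:
        return None
    combined = RWMol(Chem.CombineMols(a, b))
    i = int(rng.choice(ai))
    j = int(rng.choice(bi)) + a.GetNumAtoms()
    combined.AddBond(i, j, Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def generate_molecules(spec: FixtureSpec) -> List[str]:
    """Distinct, canonical, guaranteed-parseable SMILES; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    seen = set()
    out: List[str] = []
    attempts = 0
    max_attempts = max(200, spec.n_molecules * 200)
    while len(out) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        k = int(rng.integers(1, spec.max_fragments + 1))
        frags = [Chem.MolFromSmiles(FRAGMENT_POOL[int(rng.integers(len(FRAGMENT_POOL)))]) for _ in range(k)]
        mol = frags[0]
        ok = True
        for frag in frags[1:]:
            mol = _join(mol, frag, rng)
            if mol is None:
                ok = False
                break
        if not ok:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        seen.add(smiles)
        out.append(smiles)
    if len(out) < spec.n_molecules:
        raise RuntimeError(f"could only generate {len(out)} distinct molecules")
    return out


def radius_of_gyration(coords: np.ndarray) -> float:
    """Unweighted heavy-atom radius of gyration (Å)."""
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def synth_labels(smiles: List[str], spec: FixtureSpec, coords: Optional[List[np.ndarray]] = None) -> np.ndarray:
    """Labels for a list of valid SMILES under ``spec.label_mode``.

    ``geometry_regression`` needs per-molecule coordinates (pass the embedded
    conformers so labels match what the model sees).  Deterministic per seed.
    """
    rng = np.random.default_rng([spec.seed, 7])
    labels = np.zeros(len(smiles))
    if spec.label_mode == "motif_classification":
        pattern = Chem.MolFromSmarts(spec.motif)
        if pattern is None:
            raise ValueError(f"bad motif SMARTS {spec.motif!r}")
        for i, smi in enumerate(smiles):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"invalid SMILES {smi!r}")
            labels[i] = float(mol.HasSubstructMatch(pattern))
        flips = rng.random(len(smiles)) < spec.noise_rate
        labels[flips] = 1.0 - labels[flips]
    elif spec.label_mode == "additive_regression":
        for i, smi in enumerate(smiles):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"invalid SMILES {smi!r}")
            labels[i] = sum(ELEMENT_CONTRIBUTION.get(a.GetAtomicNum(), 0.0) for a in mol.GetAtoms())
        labels += rng.normal(0.0, spec.noise_sd, size=len(smiles))
    else:  # geometry_regression
        if coords is None:
            raise ValueError("geometry_regression labels require embedded coordinates")
        labels = np.array([radius_of_gyration(c) for c in coords])
        labels += rng.normal(0.0, spec.noise_sd, size=len(smiles))
    return labels


def make_dataset(spec: FixtureSpec, embed: bool = True) -> DatasetTable:
    """Generate molecules, embed conformers, attach labels: a ready-to-train
    table that survives dataset cleaning unchanged."""
    smiles = generate_molecules(spec)
    records = [make_record(s, [np.nan]) for s in smiles]
    data = DatasetTable(records, ["target"], spec.task_type)
    if embed or spec.label_mode == "geometry_regression":
        data = embed_dataset(data, seed=spec.seed)
    coords = [r.coords for r in data.records] if data.records and data.records[0].coords is not None else None
    labels = synth_labels(smiles, spec, coords=coords)
    for rec, y in zip(data.records, labels):
        rec.targets = np.array([y], dtype=float)
    return data


def write_fixture_csv(spec: FixtureSpec, path: str) -> DatasetTable:
    """Emit a ready-to-train CSV (smiles,target) and return the table."""
    import pandas as pd

    data = make_dataset(spec, embed=spec.label_mode == "geometry_regression")
    pd.DataFrame({
        "smiles": [r.canonical_smiles for r in data.records],
        "target": [r.targets[0] for r in data.records],
    }).to_csv(path, index=False)
    return data
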