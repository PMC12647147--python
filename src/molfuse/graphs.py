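"""Atom-graph and bond-graph featurization.

Two graph views of each molecule feed the encoder:

* the **atom graph** ``G_A`` — heavy atoms as nodes, covalent bonds as edges,
  with a 136-dimensional feature row per atom and the embedded 3D coordinates;
* the **bond graph** ``G_B`` — the line graph of ``G_A``: each bond becomes a
  node (39-dimensional feature row), and two bonds are adjacent iff they share
  exactly one atom.  Bond-node coordinates are the midpoints of the two end
  atoms, which keeps the bond channel's geometry E(3)-equivariant alongside
  the atom channel.

The 136/39 widths are the binding contract; the concrete block layout is
declared in :data:`ATOM_SCHEMA` / :data:`BOND_SCHEMA` below.  All feature
blocks are invariant under rigid motions of the coordinates (the only
geometry-derived entry, bond length, is a distance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from rdkit import Chem

from .records import MoleculeRecord

ATOM_FEATURE_DIM = 136
BOND_FEATURE_DIM = 39


@dataclass(frozen=True)
class SchemaBlock:
    name: str
    kind: str  # one-hot | binary | count | scalar
    width: int


@dataclass(frozen=True)
class FeatureSchema:
    blocks: Tuple[SchemaBlock, ...]

    @property
    def total_width(self) -> int:
        return sum(b.width for b in self.blocks)

    def slices(self) -> dict:
        out, start = {}, 0
        for b in self.blocks:
            out[b.name] = slice(start, start + b.width)
            start += b.width
        return out


_ELEMENTS_ATOM = list(range(1, 84))  # H..Bi one-hot; heavier -> "other"
_BOND_ELEMENTS = [6, 7, 8, 16, 15, 9, 17, 35, 53]  # C N O S P F Cl Br I; else "other"
_HYBRIDIZATIONS = [
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]
_RING_SIZES = [3, 4, 5, 6, 7, 8]

ATOM_SCHEMA = FeatureSchema((
    SchemaBlock("element", "one-hot", len(_ELEMENTS_ATOM) + 1),        # 84
    SchemaBlock("degree", "one-hot", 8),                               # 0..6 + other
    SchemaBlock("formal_charge", "one-hot", 6),                        # -2..2 + other
    SchemaBlock("chirality", "one-hot", len(_CHIRAL_TAGS) + 1),        # 4
    SchemaBlock("hybridization", "one-hot", len(_HYBRIDIZATIONS) + 1), # 7
    SchemaBlock("num_h", "one-hot", 6),                                # 0..4 + other
    SchemaBlock("valence", "one-hot", 8),                              # 0..6 + other
    SchemaBlock("radical_electrons", "one-hot", 4),                    # 0..2 + other
    SchemaBlock("aromatic", "binary", 1),
    SchemaBlock("in_ring", "binary", 1),
    SchemaBlock("ring_size", "binary", len(_RING_SIZES)),
    SchemaBlock("mass", "scalar", 1),                                  # amu / 100
))
assert ATOM_SCHEMA.total_width == ATOM_FEATURE_DIM

BOND_SCHEMA = FeatureSchema((
    SchemaBlock("bond_type", "one-hot", len(_BOND_TYPES) + 1),         # 5
    SchemaBlock("conjugated", "binary", 1),
    SchemaBlock("in_ring", "binary", 1),
    SchemaBlock("stereo", "one-hot", len(_STEREO)),                    # 6
    SchemaBlock("ring_size", "binary", len(_RING_SIZES)),              # 6
    SchemaBlock("end_elements", "count", len(_BOND_ELEMENTS) + 1),     # 10, symmetrized
    SchemaBlock("end_aromatic", "one-hot", 3),                         # 0/1/2 aromatic ends
    SchemaBlock("end_hybridization", "count", 4),                      # SP/SP2/SP3/other, symmetrized
    SchemaBlock("rotatable", "binary", 1),
    SchemaBlock("both_ends_in_ring", "binary", 1),
    SchemaBlock("length", "scalar", 1),                                # Angstrom
))
assert BOND_SCHEMA.total_width == BOND_FEATURE_DIM


def _one_hot(value, choices: list, width: int) -> np.ndarray:
    """One-hot with a trailing "other" slot when width == len(choices)+1."""
    v = np.zeros(width)
    try:
        v[choices.index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0
    return v


@dataclass
class AtomGraph:
    """Heavy-atom graph: symmetric 0/1 adjacency, N x 136 features, N x 3 coords."""

    adjacency: np.ndarray
    features: np.ndarray
    coords: np.ndarray
    atom_index_map: List[int]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class BondGraph:
    """Line graph of the atom graph: one node per covalent bond.

    ``bond_index_map[b]`` is the (atom_i, atom_j) pair of bond b; coordinates
    are bond midpoints.  M may be zero (e.g. methane)."""

    adjacency: np.ndarray
    features: np.ndarray
    coords: np.ndarray
    bond_index_map: List[Tuple[int, int]]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def _require_coords(record: MoleculeRecord) -> None:
    if not record.valid:
        raise ValueError("record is not a valid molecule")
    if record.coords is None:
        raise ValueError("record has no 3D coordinates; run embed_conformer first")


def atom_features(record: MoleculeRecord, atom_index: int) -> np.ndarray:
    """The 136-dim feature vector of one heavy atom."""
    mol = record.mol()
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    ring_info = mol.GetRingInfo()
    parts = [
        _one_hot(atom.GetAtomicNum(), _ELEMENTS_ATOM, 84),
        _one_hot(atom.GetDegree(), [0, 1, 2, 3, 4, 5, 6], 8),
        _one_hot(atom.GetFormalCharge(), [-2, -1, 0, 1, 2], 6),
        _one_hot(atom.GetChiralTag(), _CHIRAL_TAGS, 4),
        _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS, 7),
        _one_hot(atom.GetTotalNumHs(), [0, 1, 2, 3, 4], 6),
        _one_hot(atom.GetTotalValence(), [0, 1, 2, 3, 4, 5, 6], 8),
        _one_hot(atom.GetNumRadicalElectrons(), [0, 1, 2], 4),
        np.array([float(atom.GetIsAromatic())]),
        np.array([float(atom.IsInRing())]),
        np.array([float(ring_info.IsAtomInRingOfSize(atom_index, s)) for s in _RING_SIZES]),
        np.array([atom.GetMass() / 100.0]),
    ]
    vec = np.concatenate(parts)
    assert vec.shape == (ATOM_FEATURE_DIM,)
    return vec


def bond_features(record: MoleculeRecord, bond_index: int) -> np.ndarray:
    """The 39-dim feature vector of one covalent bond.

    End-atom blocks are symmetrized (counts over the unordered atom pair), so
    the vector is identical for (i, j) and (j, i).  The length entry is the
    Euclidean distance between the embedded end-atom coordinates.
    """
    _require_coords(record)
    mol = record.mol()
    if not 0 <= bond_index < mol.GetNumBonds():
        raise IndexError(f"bond index {bond_index} out of range")
    bond = mol.GetBondWithIdx(bond_index)
    ring_info = mol.GetRingInfo()
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()

    end_elements = np.zeros(10)
    for at in (a, b):
        try:
            end_elements[_BOND_ELEMENTS.index(at.GetAtomicNum())] += 1.0
        except ValueError:
            end_elements[-1] += 1.0
    end_hyb = np.zeros(4)
    hyb3 = [Chem.HybridizationType.SP, Chem.HybridizationType.SP2, Chem.HybridizationType.SP3]
    for at in (a, b):
        try:
            end_hyb[hyb3.index(at.GetHybridization())] += 1.0
        except ValueError:
            end_hyb[-1] += 1.0
    rotatable = (
        bond.GetBondType() == Chem.BondType.SINGLE
        and not bond.IsInRing()
        and a.GetDegree() > 1
        and b.GetDegree() > 1
    )
    length = float(np.linalg.norm(record.coords[a.GetIdx()] - record.coords[b.GetIdx()]))
    parts = [
        _one_hot(bond.GetBondType(), _BOND_TYPES, 5),
        np.array([float(bond.GetIsConjugated())]),
        np.array([float(bond.IsInRing())]),
        _one_hot(bond.GetStereo(), _STEREO, 6),
        np.array([float(ring_info.IsBondInRingOfSize(bond_index, s)) for s in _RING_SIZES]),
        end_elements,
        _one_hot(int(a.GetIsAromatic()) + int(b.GetIsAromatic()), [0, 1, 2], 3),
        end_hyb,
        np.array([float(rotatable)]),
        np.array([float(a.IsInRing() and b.IsInRing())]),
        np.array([length]),
    ]
    vec = np.concatenate(parts)
    assert vec.shape == (BOND_FEATURE_DIM,)
    return vec


def build_atom_graph(record: MoleculeRecord) -> AtomGraph:
    """Build ``G_A``: N = heavy atoms, A(i,j)=1 iff a covalent bond joins i,j."""
    _require_coords(record)
    mol = record.mol()
    n = mol.GetNumAtoms()
    adjacency = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = adjacency[j, i] = 1.0
    features = np.stack([atom_features(record, i) for i in range(n)])
    return AtomGraph(adjacency, features, np.array(record.coords, dtype=float), list(range(n)))


def build_bond_graph(record: MoleculeRecord) -> BondGraph:
    """Build ``G_B`` (the line graph): M = bonds; (b1,b2) adjacent iff the two
    bonds share exactly one atom.  M = 0 yields empty matrices."""
    _require_coords(record)
    mol = record.mol()
    m = mol.GetNumBonds()
    pairs: List[Tuple[int, int]] = []
    for bond in mol.GetBonds():
        pairs.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    adjacency = np.zeros((m, m))
    for b1 in range(m):
        for b2 in range(b1 + 1, m):
            if len(set(pairs[b1]) & set(pairs[b2])) == 1:
                adjacency[b1, b2] = adjacency[b2, b1] = 1.0
    if m:
        features = np.stack([bond_features(record, b) for b in range(m)])
        coords = np.stack([(record.coords[i] + record.coords[j]) / 2.0 for i, j in pairs])
    else:
        features = np.empty((0, BOND_FEATURE_DIM))
        coords = np.empty((0, 3))
    return BondGraph(adjacency, features, coords, pairs)


def graph_to_json(graph) -> str:
    """Serialize a graph (adjacency as an edge list, features as dense rows)."""
    edges = [[int(i), int(j)] for i, j in zip(*np.nonzero(np.triu(graph.adjacency)))]
    index_map = graph.atom_index_map if isinstance(graph, AtomGraph) else graph.bond_index_map
    return json.dumps({
        "kind": "atom" if isinstance(graph, AtomGraph) else "bond",
        "n_nodes": graph.n_nodes,
        "edges": edges,
        "features": graph.features.tolist(),
        "coords": graph.coords.tolist(),
        "index_map": [list(e) if isinstance(e, tuple) else e for e in index_map],
    })


def graph_from_json(payload: str):
    d = json.loads(payload)
    n = d["n_nodes"]
    adjacency = np.zeros((n, n))
    for i, j in d["edges"]:
        adjacency[i, j] = adjacency[j, i] = 1.0
    features = np.array(d["features"], dtype=float).reshape(n, -1) if n else np.empty((0, 0))
    coords = np.array(d["coords"], dtype=float).reshape(n, 3) if n else np.empty((0, 3))
    if d["kind"] == "atom":
        return AtomGraph(adjacency, features, coords, list(d["index_map"]))
    return BondGraph(adjacency, features, coords, [tuple(e) for e in d["index_map"]])
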