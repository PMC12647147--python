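"""Attention-based interpretability: per-atom and per-bond saliency.

The CLS (graph-representation) node attends to every node when it builds the
molecular embedding, so its attention row is a natural per-node importance
score.  The default saliency is the FINAL encoder block's CLS query row,
averaged over heads, with the CLS→CLS entry dropped and the remainder
renormalized to sum 1 — renormalization keeps maps comparable across
molecules.  Per-head and per-block extraction is available for inspection.

Maps are invariant under rigid motion of the conformer and follow atom
renumbering, because the encoder itself has those symmetries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .model import FittedModel
from .records import MoleculeRecord


@dataclass
class AttentionMap:
    """CLS attention weights for one molecule (nonnegative; atom weights sum
    to 1 after renormalization; bond weights likewise when bonds exist)."""

    atom_weights: Optional[np.ndarray]
    bond_weights: Optional[np.ndarray]
    bond_index_map: Optional[List[Tuple[int, int]]]
    source_block: int
    head_reduction: str


def _cls_row(maps: List[np.ndarray], block: int, head_reduction: str) -> np.ndarray:
    """Extract the CLS query row (entries 1..n), reduce heads, renormalize."""
    weights = maps[block]          # (heads, n+1, n+1); CLS is row/col 0
    row = weights[:, 0, 1:]        # per-head CLS -> node attention
    if head_reduction == "mean":
        row = row.mean(axis=0)
    elif head_reduction == "max":
        row = row.max(axis=0)
    elif head_reduction != "per-head":
        raise ValueError(f"unknown head_reduction {head_reduction!r}")
    total = row.sum(axis=-1, keepdims=True)
    return row / np.where(total == 0, 1.0, total)


def atom_attention(
    fitted: FittedModel,
    record: MoleculeRecord,
    block: int = -1,
    head_reduction: str = "mean",
) -> AttentionMap:
    """Per-atom CLS attention; requires a variant with the atom channel."""
    attention = fitted.attention_for(record)
    if "atom" not in attention:
        raise ValueError(f"variant {fitted.config.variant!r} has no atom attention channel")
    weights = _cls_row(attention["atom"], block, head_reduction)
    return AttentionMap(weights, None, None, block, head_reduction)


def bond_attention(
    fitted: FittedModel,
    record: MoleculeRecord,
    block: int = -1,
    head_reduction: str = "mean",
) -> AttentionMap:
    """Per-bond CLS attention, indexed by the bond graph's (atom_i, atom_j)
    pairs.  A bondless molecule yields an empty map with a warning."""
    from .graphs import build_bond_graph

    attention = fitted.attention_for(record)
    if "bond" not in attention:
        raise ValueError(f"variant {fitted.config.variant!r} has no bond attention channel")
    bond_graph = build_bond_graph(record)
    if bond_graph.n_nodes == 0:
        warnings.warn(f"molecule {record.canonical_smiles!r} has no bonds; empty attention map")
        return AttentionMap(None, np.empty(0), [], block, head_reduction)
    weights = _cls_row(attention["bond"], block, head_reduction)
    return AttentionMap(None, weights, bond_graph.bond_index_map, block, head_reduction)


def export_attention(
    attn_map: AttentionMap,
    record: MoleculeRecord,
    path: str,
    depiction_path: Optional[str] = None,
) -> None:
    """Write the map as JSON (atom index, element, weight; bond pair, weight);
    optionally also a 2D SVG depiction with a monotone color ramp (darker =
    higher weight)."""
    mol = record.mol()
    payload: dict = {"smiles": record.canonical_smiles}
    if attn_map.atom_weights is not None:
        if len(attn_map.atom_weights) != mol.GetNumAtoms():
            raise ValueError("atom weight length does not match molecule")
        payload["atoms"] = [
            {"index": i, "element": mol.GetAtomWithIdx(i).GetSymbol(), "weight": float(w)}
            for i, w in enumerate(attn_map.atom_weights)
        ]
    if attn_map.bond_weights is not None:
        payload["bonds"] = [
            {"atoms": list(pair), "weight": float(w)}
            for pair, w in zip(attn_map.bond_index_map or [], attn_map.bond_weights)
        ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if depiction_path is not None:
        depict_attention(attn_map, record, depiction_path)


def weight_to_color(weight: float, max_weight: float) -> Tuple[float, float, float]:
    """Monotone white→red ramp: higher weight, darker color (lower RGB sum)."""
    t = 0.0 if max_weight <= 0 else min(weight / max_weight, 1.0)
    return (1.0, 1.0 - 0.85 * t, 1.0 - 0.85 * t)


def depict_attention(attn_map: AttentionMap, record: MoleculeRecord, path: str) -> None:
    """2D SVG with atoms (and bonds, when present) shaded by attention."""
    from rdkit.Chem.Draw import rdMolDraw2D

    mol = record.mol()
    drawer = rdMolDraw2D.MolDraw2DSVG(400, 400)
    highlight_atoms, atom_colors = [], {}
    highlight_bonds, bond_colors = [], {}
    if attn_map.atom_weights is not None and len(attn_map.atom_weights):
        mx = float(np.max(attn_map.atom_weights))
        for i, w in enumerate(attn_map.atom_weights):
            highlight_atoms.append(i)
            atom_colors[i] = weight_to_color(float(w), mx)
    if attn_map.bond_weights is not None and len(attn_map.bond_weights):
        mx = float(np.max(attn_map.bond_weights))
        for pair, w in zip(attn_map.bond_index_map or [], attn_map.bond_weights):
            bond = mol.GetBondBetweenAtoms(*pair)
            if bond is not None:
                highlight_bonds.append(bond.GetIdx())
                bond_colors[bond.GetIdx()] = weight_to_color(float(w), mx)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol,
        highlightAtoms=highlight_atoms, highlightAtomColors=atom_colors,
        highlightBonds=highlight_bonds, highlightBondColors=bond_colors,
    )
    drawer.FinishDrawing()
    with open(path, "w") as fh:
        fh.write(drawer.GetDrawingText())
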