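"""The GCN-Transformer equivariant encoder with fingerprint fusion.

Architecture (per enabled graph channel — atom graph and/or bond graph):

1. a stack of graph-convolution layers ``H' = ReLU(Â H W)`` over the
   symmetric-normalized adjacency ``Â = D̃^{-1/2}(A+I)D̃^{-1/2}`` injects local
   topology and stands in for positional encoding;
2. a learned CLS (graph-representation) row is prepended;
3. ``encoder_blocks`` repetitions of [equivariant graph operation; multi-head
   self-attention with residual + layer norm].  The equivariant operation
   updates node features from squared pairwise distances and displaces
   coordinates along relative positions (CLS excluded from geometry), so the
   final CLS embedding is invariant to rigid motions of the conformer.

The fingerprint channel is a feed-forward encoder over a concatenated
fingerprint panel.  Channel embeddings are concatenated and a two-layer FNN
head emits one output per task (logits for classification, standardized
values for regression).

Seven variants cover the ablation grid: ``GCN`` (convolution stack + mean
pooling, no transformer), ``Atom``, ``AtomBond``, ``FP``, ``AtomBondFP``,
``Full`` (everything incl. the equivariant operation) and ``Mini`` (Full
minus the equivariant operation — the fast preset).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import fingerprints as fp
from .graphs import (
    ATOM_FEATURE_DIM,
    ATOM_SCHEMA,
    BOND_FEATURE_DIM,
    BOND_SCHEMA,
    AtomGraph,
    BondGraph,
    build_atom_graph,
    build_bond_graph,
)
from .nn import (
    Adam,  # noqa: F401  (re-exported for training)
    Dropout,
    EGNNLayer,
    GCNLayer,
    LayerNorm,
    Linear,
    MLP,
    Module,
    MultiHeadSelfAttention,
    Tensor,
    concat,
    no_grad,
)
from .records import CLASSIFICATION, REGRESSION, MoleculeRecord

VARIANTS = ("GCN", "Atom", "AtomBond", "FP", "AtomBondFP", "Full", "Mini")

# which channels each variant instantiates; the equivariant operation is
# enabled only for Full
_VARIANT_CHANNELS = {
    "GCN": {"atom"},
    "Atom": {"atom"},
    "AtomBond": {"atom", "bond"},
    "FP": {"fp"},
    "AtomBondFP": {"atom", "bond", "fp"},
    "Full": {"atom", "bond", "fp"},
    "Mini": {"atom", "bond", "fp"},
}


@dataclass
class ModelConfig:
    """Architecture + channel configuration.

    ``attention_heads`` defaults to 4 per the reference architecture; unstated
    depths/widths use the package defaults below and are all exposed here.
    """

    variant: str = "Full"
    task_type: str = CLASSIFICATION
    n_tasks: int = 1
    hidden_dim: int = 256
    gcn_layers: int = 2
    encoder_blocks: int = 3
    attention_heads: int = 4
    dropout: float = 0.1
    fingerprint_families: Optional[List[str]] = None
    fp_hidden: int = 256
    head_hidden: int = 256
    egnn_neighborhood: str = "full"  # "full" | "bonded"
    coord_update: str = "mean"       # "mean" | "sum"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.hidden_dim % self.attention_heads:
            raise ValueError("attention_heads must divide hidden_dim")
        if self.task_type not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"bad task_type {self.task_type!r}")
        if self.fingerprint_families is None:
            self.fingerprint_families = fp.default_families(self.task_type)

    @property
    def channels(self) -> set:
        return _VARIANT_CHANNELS[self.variant]

    @property
    def use_egnn(self) -> bool:
        return self.variant == "Full"

    @property
    def fp_dim(self) -> int:
        return fp.panel_width(self.fingerprint_families)


def make_variant(name: str, **overrides) -> ModelConfig:
    """Config for one of the seven named architecture variants."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")
    return ModelConfig(variant=name, **overrides)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization D̃^{-1/2}(A+I)D̃^{-1/2} with D̃ the degree
    matrix of A+I.  Requires a square symmetric 0/1 matrix with zero diagonal."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(H: np.ndarray, A_hat: np.ndarray, W: np.ndarray, activation: str = "relu") -> np.ndarray:
    """Functional single GCN layer (numpy in/out): activation(Â H W)."""
    if H.shape[0] != A_hat.shape[0]:
        raise ValueError("H rows must match A_hat rows")
    out = A_hat @ H @ W
    return np.maximum(out, 0.0) if activation == "relu" else out


@dataclass
class _GraphCache:
    """Pre-computed constants reused every forward pass."""

    A_hat: Optional[np.ndarray]
    edge_src: np.ndarray
    edge_dst: np.ndarray


@dataclass
class FeaturizedMolecule:
    """Per-molecule model inputs, cached once before training."""

    record: MoleculeRecord
    atom_graph: Optional[AtomGraph] = None
    bond_graph: Optional[BondGraph] = None
    fp_raw: Optional[np.ndarray] = None
    atom_cache: Optional["_GraphCache"] = None
    bond_cache: Optional["_GraphCache"] = None


def _make_cache(graph, mode: str) -> _GraphCache:
    if graph.n_nodes == 0:
        empty = np.empty(0, dtype=int)
        return _GraphCache(None, empty, empty)
    src, dst = _edge_index(graph.adjacency, mode)
    return _GraphCache(normalize_adjacency(graph.adjacency), src, dst)


def featurize_record(record: MoleculeRecord, config: ModelConfig) -> FeaturizedMolecule:
    """Build only the inputs the variant needs (graphs require coordinates)."""
    fm = FeaturizedMolecule(record)
    if "atom" in config.channels:
        fm.atom_graph = build_atom_graph(record)
        fm.atom_cache = _make_cache(fm.atom_graph, config.egnn_neighborhood)
    if "bond" in config.channels:
        fm.bond_graph = build_bond_graph(record)
        fm.bond_cache = _make_cache(fm.bond_graph, config.egnn_neighborhood)
    if "fp" in config.channels:
        fm.fp_raw = fp.fingerprint_panel(record, config.fingerprint_families).vector
    return fm


def _edge_index(adjacency: np.ndarray, mode: str) -> Tuple[np.ndarray, np.ndarray]:
    """Directed edge lists (dst receives from src is (i <- j): arrays i, j)."""
    n = adjacency.shape[0]
    if mode == "full":
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = i != j
        return i[mask], j[mask]
    i, j = np.nonzero(adjacency)
    return i, j


class _GraphChannel(Module):
    """One graph channel: GCN stack -> CLS prepend -> encoder blocks."""

    def __init__(self, rng: np.random.Generator, config: ModelConfig, in_dim: int):
        super().__init__()
        self.config = config
        hidden = config.hidden_dim
        dims = [in_dim] + [hidden] * config.gcn_layers
        self.gcn = [self.add_module(GCNLayer(rng, a, b)) for a, b in zip(dims[:-1], dims[1:])]
        self.cls = self.add_param(rng.normal(0.0, 0.1, size=(1, hidden)))
        self.blocks = []
        for _ in range(config.encoder_blocks):
            egnn = EGNNLayer(rng, hidden, config.coord_update) if config.use_egnn else None
            if egnn is not None:
                self.add_module(egnn)
            attn = self.add_module(MultiHeadSelfAttention(rng, hidden, config.attention_heads))
            ln = self.add_module(LayerNorm(hidden))
            self.blocks.append((egnn, attn, ln))

    def __call__(self, graph, cache: Optional[_GraphCache] = None) -> Tuple[Tensor, List[np.ndarray]]:
        """Return (CLS embedding as a 1 x hidden tensor, per-block attention
        weights of shape (heads, n+1, n+1); CLS is row/column 0)."""
        n = graph.n_nodes
        if cache is None:
            cache = _make_cache(graph, self.config.egnn_neighborhood)
        if n > 0:
            H = Tensor(graph.features)
            for layer in self.gcn:
                H = layer(H, cache.A_hat)
            H = concat([self.cls, H], axis=0)
            X = Tensor(np.asarray(graph.coords, dtype=float))
        else:
            # bondless molecule: the channel degenerates to attention over CLS alone
            H, X = self.cls, None
        maps: List[np.ndarray] = []
        for egnn, attn, ln in self.blocks:
            if egnn is not None and n > 0:
                nodes, X = egnn(H[1:, :], X, cache.edge_src, cache.edge_dst)
                H = concat([H[0:1, :], nodes], axis=0)
            H = ln(H + attn(H))
            maps.append(attn.last_weights)
        return H[0:1, :], maps

    def pooled(self, graph, cache: Optional[_GraphCache] = None) -> Tensor:
        """GCN-baseline readout: convolution stack + mean pooling, no transformer."""
        A_hat = cache.A_hat if cache is not None else normalize_adjacency(graph.adjacency)
        H = Tensor(graph.features)
        for layer in self.gcn:
            H = layer(H, A_hat)
        return H.mean(axis=0, keepdims=True)


class _FPChannel(Module):
    """Fingerprint FNN encoder: panel -> hidden -> hidden embedding."""

    def __init__(self, rng: np.random.Generator, config: ModelConfig):
        super().__init__()
        self.l1 = self.add_module(Linear(rng, config.fp_dim, config.fp_hidden))
        self.l2 = self.add_module(Linear(rng, config.fp_hidden, config.hidden_dim))
        self.dropout = Dropout(config.dropout)

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        h = self.dropout(self.l1(x).relu(), rng, training)
        return self.l2(h).relu()


class MolFuseNetwork(Module):
    """All enabled channels plus the fused two-layer FNN prediction head."""

    def __init__(self, rng: np.random.Generator, config: ModelConfig):
        super().__init__()
        self.config = config
        self.atom_channel = None
        self.bond_channel = None
        self.fp_channel = None
        n_channels = 0
        if "atom" in config.channels:
            self.atom_channel = self.add_module(_GraphChannel(rng, config, ATOM_FEATURE_DIM))
            n_channels += 1
        if "bond" in config.channels:
            self.bond_channel = self.add_module(_GraphChannel(rng, config, BOND_FEATURE_DIM))
            n_channels += 1
        if "fp" in config.channels:
            self.fp_channel = self.add_module(_FPChannel(rng, config))
            n_channels += 1
        self.head = self.add_module(MLP(rng, [config.hidden_dim * n_channels, config.head_hidden, config.n_tasks]))
        self.head_dropout = Dropout(config.dropout)

    def _graph_embedding(self, fm: FeaturizedMolecule) -> Tuple[List[Tensor], Dict[str, List[np.ndarray]]]:
        parts: List[Tensor] = []
        attention: Dict[str, List[np.ndarray]] = {}
        if self.atom_channel is not None:
            graph = fm.atom_graph
            if graph is None or graph.n_nodes == 0:
                raise ValueError("atom channel requires a non-empty atom graph")
            if self.config.variant == "GCN":
                parts.append(self.atom_channel.pooled(graph, fm.atom_cache))
            else:
                emb, maps = self.atom_channel(graph, fm.atom_cache)
                parts.append(emb)
                attention["atom"] = maps
        if self.bond_channel is not None:
            emb, maps = self.bond_channel(fm.bond_graph, fm.bond_cache)
            parts.append(emb)
            attention["bond"] = maps
        return parts, attention

    def forward_batch(
        self,
        fms: Sequence[FeaturizedMolecule],
        fp_scaled: Optional[np.ndarray] = None,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
        want_attention: bool = False,
    ) -> Tuple[Tensor, Optional[List[Dict[str, List[np.ndarray]]]]]:
        """Logits (B x n_tasks) for a batch.  Graph channels run per molecule
        (graphs have different sizes); the fingerprint channel and head run
        batched.  Attention maps are collected only on request."""
        attention: List[Dict[str, List[np.ndarray]]] = []
        blocks: List[Tensor] = []
        per_mol: List[List[Tensor]] = []
        for fm in fms:
            parts, attn = self._graph_embedding(fm)
            per_mol.append(parts)
            if want_attention:
                attention.append(attn)
        if per_mol and per_mol[0]:
            graph_rows = [concat(parts, axis=1) if len(parts) > 1 else parts[0] for parts in per_mol]
            blocks.append(concat(graph_rows, axis=0))
        if self.fp_channel is not None:
            if fp_scaled is None:
                fp_scaled = np.stack([fm.fp_raw for fm in fms])
            blocks.append(self.fp_channel(Tensor(fp_scaled), training, rng))
        z = concat(blocks, axis=1) if len(blocks) > 1 else blocks[0]
        z = self.head_dropout(z, rng, training)
        return self.head(z), attention if want_attention else None

    def forward_one(
        self,
        fm: FeaturizedMolecule,
        fp_scaled: Optional[np.ndarray] = None,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[Tensor, Dict[str, List[np.ndarray]]]:
        """Logits (1 x n_tasks) and per-channel attention maps for one molecule."""
        if fp_scaled is not None:
            fp_scaled = fp_scaled.reshape(1, -1)
        logits, attention = self.forward_batch(
            [fm], fp_scaled=fp_scaled, training=training, rng=rng, want_attention=True,
        )
        return logits, attention[0]


def schema_hash(config: ModelConfig) -> str:
    """Fingerprint of the feature contract a checkpoint was trained under."""
    payload = json.dumps({
        "atom": [(b.name, b.kind, b.width) for b in ATOM_SCHEMA.blocks],
        "bond": [(b.name, b.kind, b.width) for b in BOND_SCHEMA.blocks],
        "families": list(config.fingerprint_families),
    })
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FittedModel:
    """A trained network plus the preprocessing state needed to apply it."""

    config: ModelConfig
    network: MolFuseNetwork
    fp_mean: Optional[np.ndarray] = None
    fp_std: Optional[np.ndarray] = None
    target_mean: Optional[np.ndarray] = None
    target_std: Optional[np.ndarray] = None
    history: List[dict] = field(default_factory=list)
    schema: str = ""

    def scale_fp(self, raw: np.ndarray) -> np.ndarray:
        if self.fp_mean is None:
            return raw
        return (raw - self.fp_mean) / self.fp_std

    def _finalize(self, logits: np.ndarray) -> np.ndarray:
        if self.config.task_type == CLASSIFICATION:
            return 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
        out = logits
        if self.target_mean is not None:
            out = out * self.target_std + self.target_mean
        return out

    def predict_features(self, features: Sequence[FeaturizedMolecule]) -> np.ndarray:
        """Predictions for featurized molecules: probabilities in [0,1] for
        classification, original-unit values for regression."""
        rows = []
        with no_grad():
            for start in range(0, len(features), 256):
                chunk = features[start:start + 256]
                scaled = None
                if chunk[0].fp_raw is not None:
                    scaled = self.scale_fp(np.stack([fm.fp_raw for fm in chunk]))
                logits, _ = self.network.forward_batch(chunk, fp_scaled=scaled)
                rows.append(logits.data)
        return self._finalize(np.concatenate(rows, axis=0))

    def predict_records(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        return self.predict_features([featurize_record(r, self.config) for r in records])

    def attention_for(self, record: MoleculeRecord) -> Dict[str, List[np.ndarray]]:
        fm = featurize_record(record, self.config)
        with no_grad():
            scaled = self.scale_fp(fm.fp_raw) if fm.fp_raw is not None else None
            _, attention = self.network.forward_one(fm, fp_scaled=scaled)
        return attention


def forward(records: Sequence[MoleculeRecord], fitted: FittedModel) -> np.ndarray:
    """Batch prediction entry point (n_molecules x n_tasks)."""
    return fitted.predict_records(records)


def save_checkpoint(fitted: FittedModel, path: str) -> None:
    """Single-archive checkpoint: config JSON, parameter tensors, scalers and
    the feature-schema hash."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(fitted.network.parameters())}
    for name in ("fp_mean", "fp_std", "target_mean", "target_std"):
        val = getattr(fitted, name)
        if val is not None:
            arrays[name] = val
    meta = {"config": asdict(fitted.config), "schema": fitted.schema, "history": fitted.history}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str) -> FittedModel:
    """Load a checkpoint; refuses archives whose feature-schema hash does not
    match the running code's schema."""
    archive = np.load(path)
    meta = json.loads(bytes(archive["meta_json"]).decode())
    config = ModelConfig(**meta["config"])
    expected = schema_hash(config)
    if meta["schema"] and meta["schema"] != expected:
        raise ValueError(
            f"checkpoint feature schema {meta['schema']} does not match current schema {expected}"
        )
    network = MolFuseNetwork(np.random.default_rng(0), config)
    for i, p in enumerate(network.parameters()):
        stored = archive[f"param_{i}"]
        if stored.shape != p.data.shape:
            raise ValueError("checkpoint parameter shapes do not match config")
        p.data = stored.astype(np.float64)
    fitted = FittedModel(config=config, network=network, history=meta["history"], schema=meta["schema"])
    for name in ("fp_mean", "fp_std", "target_mean", "target_std"):
        if name in archive:
            setattr(fitted, name, archive[name])
    return fitted
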