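"""scikit-learn-style estimators over the multi-scale encoder.

:class:`MolFuseClassifier` and :class:`MolFuseRegressor` take SMILES strings
as samples (a list/array of str, or pre-built :class:`MoleculeRecord`
objects) and compose with sklearn model selection::

    clf = MolFuseClassifier(variant="Full", hidden_dim=64, random_state=0)
    clf.fit(smiles_list, y)
    proba = clf.predict_proba(new_smiles)

``fit`` canonicalizes and validates the molecules, embeds one
force-field-optimized conformer each (for variants with a graph channel),
carves an internal validation fraction out of the training data for early
stopping, and trains with Adam.  Fitted state lives on ``model_`` (a
:class:`~molfuse.model.FittedModel`) plus the usual sklearn conventions
(``classes_``, ``n_features_in_`` is not applicable to string input and is
omitted).  Multi-task labels are supported as an ``(n, n_tasks)`` array with
NaN marking missing labels.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from sklearn.base import BaseEstimator

from .model import ModelConfig, make_variant
from .records import (
    CLASSIFICATION,
    REGRESSION,
    DatasetTable,
    MoleculeRecord,
    embed_dataset,
    make_record,
)
from .training import Split, TrainSettings, train


def _to_records(X, y: Optional[np.ndarray]) -> List[MoleculeRecord]:
    n_tasks = 1 if y is None or y.ndim == 1 else y.shape[1]
    records = []
    for i, item in enumerate(X):
        if isinstance(item, MoleculeRecord):
            rec = item
            if y is not None:
                targets = np.atleast_1d(np.asarray(y[i], dtype=float))
                rec = MoleculeRecord(rec.raw_smiles, rec.canonical_smiles, targets,
                                     rec.coords, rec.valid, rec.used_2d_fallback)
        else:
            targets = np.full(n_tasks, np.nan) if y is None else np.atleast_1d(np.asarray(y[i], dtype=float))
            rec = make_record(str(item), targets)
        if not rec.valid:
            raise ValueError(f"sample {i} is not a valid molecule: {rec.raw_smiles!r}")
        records.append(rec)
    return records


class _MolFuseBase(BaseEstimator):
    _task_type: str = CLASSIFICATION

    def __init__(
        self,
        variant: str = "Full",
        hidden_dim: int = 256,
        gcn_layers: int = 2,
        encoder_blocks: int = 3,
        attention_heads: int = 4,
        dropout: float = 0.1,
        fingerprint_families: Optional[List[str]] = None,
        fp_hidden: int = 256,
        head_hidden: int = 256,
        egnn_neighborhood: str = "full",
        coord_update: str = "mean",
        force_field: str = "uff",
        max_epochs: int = 100,
        batch_size: int = 32,
        lr: float = 1e-3,
        patience: int = 20,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.variant = variant
        self.hidden_dim = hidden_dim
        self.gcn_layers = gcn_layers
        self.encoder_blocks = encoder_blocks
        self.attention_heads = attention_heads
        self.dropout = dropout
        self.fingerprint_families = fingerprint_families
        self.fp_hidden = fp_hidden
        self.head_hidden = head_hidden
        self.egnn_neighborhood = egnn_neighborhood
        self.coord_update = coord_update
        self.force_field = force_field
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _config(self, n_tasks: int) -> ModelConfig:
        return make_variant(
            self.variant,
            task_type=self._task_type,
            n_tasks=n_tasks,
            hidden_dim=self.hidden_dim,
            gcn_layers=self.gcn_layers,
            encoder_blocks=self.encoder_blocks,
            attention_heads=self.attention_heads,
            dropout=self.dropout,
            fingerprint_families=(
                list(self.fingerprint_families) if self.fingerprint_families else None
            ),
            fp_hidden=self.fp_hidden,
            head_hidden=self.head_hidden,
            egnn_neighborhood=self.egnn_neighborhood,
            coord_update=self.coord_update,
        )

    def _prepare(self, X, y: Optional[np.ndarray], config: ModelConfig) -> DatasetTable:
        records = _to_records(X, y)
        n_tasks = len(records[0].targets)
        data = DatasetTable(records, [f"task_{t}" for t in range(n_tasks)], self._task_type)
        if config.channels - {"fp"}:
            data = embed_dataset(data, seed=self.random_state, force_field=self.force_field)
        return data

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        n_tasks = 1 if y.ndim == 1 else y.shape[1]
        config = self._config(n_tasks)
        data = self._prepare(X, y, config)
        n = len(data)
        rng = np.random.default_rng(self.random_state)
        n_val = max(1, int(round(self.val_fraction * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        split = Split(
            train=perm[n_val:].tolist(), val=perm[:n_val].tolist(), test=[],
            method="random", seed=self.random_state, ratio=(1 - self.val_fraction, self.val_fraction, 0.0),
        )
        settings = TrainSettings(
            max_epochs=self.max_epochs, batch_size=self.batch_size,
            lr=self.lr, patience=self.patience,
        )
        self.model_ = train(config, data, split, settings, seed=self.random_state)
        self.n_tasks_ = n_tasks
        self.history_ = self.model_.history
        return self

    def _predict_raw(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        config = self.model_.config
        records = _to_records(X, None)
        data = DatasetTable(records, [f"task_{t}" for t in range(self.n_tasks_)], self._task_type)
        if config.channels - {"fp"}:
            data = embed_dataset(data, seed=self.random_state, force_field=self.force_field)
        return self.model_.predict_records(data.records)


class MolFuseClassifier(_MolFuseBase):
    """Binary (optionally multi-task) molecular property classifier."""

    _task_type = CLASSIFICATION

    def fit(self, X, y):
        super().fit(X, y)
        self.classes_ = np.array([0.0, 1.0])
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) class probabilities for single-task input, or an
        (n, n_tasks) matrix of positive-class probabilities for multi-task."""
        p = self._predict_raw(X)
        if self.n_tasks_ == 1:
            p1 = p[:, 0]
            return np.column_stack([1.0 - p1, p1])
        return p

    def predict(self, X) -> np.ndarray:
        p = self._predict_raw(X)
        labels = (p >= 0.5).astype(float)
        return labels[:, 0] if self.n_tasks_ == 1 else labels

    def score(self, X, y) -> float:
        """Mean ROC-AUC over tasks (the field's standard metric)."""
        from .training import roc_auc

        p = self._predict_raw(X)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        vals = []
        for t in range(self.n_tasks_):
            mask = ~np.isnan(y[:, t])
            vals.append(roc_auc(p[mask, t], y[mask, t]))
        return float(np.mean(vals))


class MolFuseRegressor(_MolFuseBase):
    """Continuous molecular property regressor (original target units)."""

    _task_type = REGRESSION

    def predict(self, X) -> np.ndarray:
        p = self._predict_raw(X)
        return p[:, 0] if self.n_tasks_ == 1 else p

    def score(self, X, y) -> float:
        """R² (sklearn convention); RMSE is available via molfuse.training.rmse."""
        from sklearn.metrics import r2_score

        return float(r2_score(np.asarray(y, dtype=float), self.predict(X)))
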