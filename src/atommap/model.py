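"""The atom-mapper estimator: configuration, training, and prediction.

:class:`AtomMapper` is a scikit-learn-style estimator.  ``fit`` takes a
list of :class:`~atommap.reaction_io.ReactionRecord` and a list of gold
:class:`~atommap.mapping.AtomMapping`; ``predict_proba`` returns one
row-stochastic :class:`~atommap.mapping.MappingProbabilityMatrix` per
reaction and ``predict`` decodes it greedily into an atom map.

Architecture: a shared message-passing stack encodes reactant and product
graphs; product features then attend to reactant features through
multi-head cross-attention blocks; a single-head attention classifier
yields ``p(reactant atom | product atom)``.  Training minimizes the mean
negative log-probability of the gold pairs with Adam, halving the learning
rate whenever the validation loss fails to improve.

Reactions in a batch are merged into one block-diagonal graph with an
additive attention mask, so a batch is a single forward pass.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from sklearn.base import BaseEstimator

from .features import FeatureConfig, MolecularGraph, featurize
from .mapping import AtomMapping, MappingProbabilityMatrix, decode_greedy
from .nn.autograd import Tensor, gather_pairs
from .nn.layers import (
    NEG_INF,
    classifier_scores,
    cross_attend,
    init_parameters,
    mpnn_encode,
)
from .reaction_io import ReactionRecord

logger = logging.getLogger(__name__)

__all__ = ["MapperNetConfig", "TrainConfig", "AtomMapper", "train_mapper"]


@dataclass(frozen=True)
class MapperNetConfig:
    """Network hyperparameters.

    Three message-passing layers and three reaction-attention blocks with
    eight heads; the hidden dimension defaults to 320 and must be divisible
    by the head count.
    """

    mpnn_layers: int = 3
    attention_blocks: int = 3
    n_heads: int = 8
    hidden_dim: int = 320
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if not (self.mpnn_layers > 0 and self.attention_blocks > 0 and self.n_heads > 0):
            raise ValueError("layer counts must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam, plateau-halved learning rate)."""

    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 1e-6
    lr_decay_factor: float = 0.5
    plateau_patience: int = 1
    grad_clip_norm: float = 20.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be positive, weight_decay >= 0")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1)")
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be positive")


class _PackedBatch:
    """Several reactions merged into one block-diagonal problem."""

    def __init__(
        self,
        graphs: Sequence[tuple[MolecularGraph, MolecularGraph]],
        mappings: Optional[Sequence[AtomMapping]] = None,
    ):
        r_feats, p_feats = [], []
        r_src, r_dst, r_bf = [], [], []
        p_src, p_dst, p_bf = [], [], []
        self.p_slices: list[tuple[int, int]] = []
        self.r_slices: list[tuple[int, int]] = []
        ro = po = 0
        for rg, pg in graphs:
            r_feats.append(rg.atom_features)
            p_feats.append(pg.atom_features)
            r_src.append(rg.src + ro)
            r_dst.append(rg.dst + ro)
            r_bf.append(rg.bond_features)
            p_src.append(pg.src + po)
            p_dst.append(pg.dst + po)
            p_bf.append(pg.bond_features)
            self.r_slices.append((ro, ro + rg.n_atoms))
            self.p_slices.append((po, po + pg.n_atoms))
            ro += rg.n_atoms
            po += pg.n_atoms
        self.r_atom_features = np.concatenate(r_feats)
        self.p_atom_features = np.concatenate(p_feats)
        self.r_src = np.concatenate(r_src)
        self.r_dst = np.concatenate(r_dst)
        self.r_bond_features = np.concatenate(r_bf)
        self.p_src = np.concatenate(p_src)
        self.p_dst = np.concatenate(p_dst)
        self.p_bond_features = np.concatenate(p_bf)
        # additive mask: 0 inside a reaction's block, -inf across reactions
        self.mask = np.full((po, ro), NEG_INF)
        for (pa, pb), (ra, rb) in zip(self.p_slices, self.r_slices):
            self.mask[pa:pb, ra:rb] = 0.0
        if mappings is not None:
            rows, cols = [], []
            for (pa, _), (ra, _), m in zip(self.p_slices, self.r_slices, mappings):
                for p, r in m.pairs:
                    rows.append(pa + p)
                    cols.append(ra + r)
            self.gold_rows = np.asarray(rows, dtype=np.intp)
            self.gold_cols = np.asarray(cols, dtype=np.intp)


def _forward(
    params: dict[str, Tensor],
    cfg: MapperNetConfig,
    batch: _PackedBatch,
    training: bool,
    rng: Optional[np.random.Generator],
) -> Tensor:
    h_r = mpnn_encode(
        params, batch.r_atom_features, batch.r_src, batch.r_dst,
        batch.r_bond_features, cfg.mpnn_layers,
    )
    h_p = mpnn_encode(
        params, batch.p_atom_features, batch.p_src, batch.p_dst,
        batch.p_bond_features, cfg.mpnn_layers,
    )
    h_p = cross_attend(
        params, h_p, h_r, cfg.attention_blocks, cfg.n_heads,
        mask=batch.mask, dropout=cfg.dropout, training=training, rng=rng,
    )
    return classifier_scores(params, h_r, h_p, mask=batch.mask)


def _loss(P: Tensor, batch: _PackedBatch) -> Tensor:
    picked = gather_pairs(P, batch.gold_rows, batch.gold_cols)
    return -((picked + 1e-12).log().mean())


def _adam_step(
    params: dict[str, Tensor],
    state: dict[str, tuple[np.ndarray, np.ndarray]],
    lr: float,
    weight_decay: float,
    clip_norm: float,
    step: int,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    grads = {}
    total = 0.0
    for name, p in params.items():
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        g = g + weight_decay * p.data
        grads[name] = g
        total += float((g * g).sum())
    norm = math.sqrt(total)
    scale = clip_norm / norm if norm > clip_norm else 1.0
    for name, p in params.items():
        g = grads[name] * scale
        m, v = state[name]
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        state[name] = (m, v)
        mhat = m / (1 - beta1**step)
        vhat = v / (1 - beta2**step)
        p.data -= lr * mhat / (np.sqrt(vhat) + eps)
        p.grad = None


def _validate_labels(
    records: Sequence[ReactionRecord], mappings: Sequence[AtomMapping]
) -> None:
    if len(records) != len(mappings):
        raise ValueError("records and mappings must align")
    for rec, m in zip(records, mappings):
        if not m.is_total_over(rec.n_product_atoms):
            raise ValueError(
                f"labeled mapping for reaction {rec.reaction_id!r} leaves "
                "product atoms unmapped"
            )


class AtomMapper(BaseEstimator):
    """Graph-neural atom-to-atom mapper (scikit-learn estimator API).

    Parameters mirror :class:`MapperNetConfig` and :class:`TrainConfig`;
    ``d`` below is ``hidden_dim``.  After ``fit`` the trained weights live
    in ``params_`` and the per-epoch log in ``training_log_``.

    Examples
    --------
    >>> mapper = AtomMapper(hidden_dim=64, epochs=20, random_state=0)
    >>> mapper.fit(train_records, train_mappings)      # doctest: +SKIP
    >>> mapper.predict([record])                        # doctest: +SKIP
    [AtomMapping(pairs=((0, 0), (1, 1), ...), ...)]
    """

    def __init__(
        self,
        hidden_dim: int = 320,
        mpnn_layers: int = 3,
        attention_blocks: int = 3,
        n_heads: int = 8,
        dropout: float = 0.1,
        epochs: int = 100,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-6,
        lr_decay_factor: float = 0.5,
        plateau_patience: int = 1,
        grad_clip_norm: float = 20.0,
        enforce_element_match: bool = True,
        random_state: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.mpnn_layers = mpnn_layers
        self.attention_blocks = attention_blocks
        self.n_heads = n_heads
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.lr_decay_factor = lr_decay_factor
        self.plateau_patience = plateau_patience
        self.grad_clip_norm = grad_clip_norm
        self.enforce_element_match = enforce_element_match
        self.random_state = random_state

    # --- config plumbing -------------------------------------------------
    def _net_config(self) -> MapperNetConfig:
        return MapperNetConfig(
            mpnn_layers=self.mpnn_layers,
            attention_blocks=self.attention_blocks,
            n_heads=self.n_heads,
            hidden_dim=self.hidden_dim,
            dropout=self.dropout,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            lr_decay_factor=self.lr_decay_factor,
            plateau_patience=self.plateau_patience,
            grad_clip_norm=self.grad_clip_norm,
            random_seed=self.random_state,
        )

    # --- fitting ---------------------------------------------------------
    def fit(
        self,
        X: Sequence[ReactionRecord],
        y: Sequence[AtomMapping],
        validation: Optional[
            tuple[Sequence[ReactionRecord], Sequence[AtomMapping]]
        ] = None,
    ) -> "AtomMapper":
        """Train on labeled reactions.

        ``validation`` is an optional held-out ``(records, mappings)`` pair
        driving the learning-rate plateau schedule; without it the training
        loss is used.  The caller owns the split.
        """
        net_cfg = self._net_config()
        train_cfg = self._train_config()
        _validate_labels(X, y)
        if validation is not None:
            _validate_labels(*validation)
        rng = np.random.default_rng(train_cfg.random_seed)
        self.feature_config_ = FeatureConfig()
        graphs = [featurize(r, self.feature_config_) for r in X]
        self.params_ = init_parameters(
            rng,
            self.feature_config_.atom_dim,
            self.feature_config_.bond_dim,
            net_cfg.hidden_dim,
            net_cfg.mpnn_layers,
            net_cfg.attention_blocks,
        )
        # plateau scheduling runs on a clean inference-mode pass: over the
        # validation split when given, else over the training set itself.
        # packed in batch-size chunks — the attention mask is quadratic in
        # the number of atoms per pack, so one giant pack is not an option
        def _chunked(gs, ms):
            return [
                _PackedBatch(gs[i : i + train_cfg.batch_size],
                             ms[i : i + train_cfg.batch_size])
                for i in range(0, len(gs), train_cfg.batch_size)
            ]

        if validation is not None and len(validation[0]):
            val_graphs = [featurize(r, self.feature_config_) for r in validation[0]]
            val_batches = _chunked(val_graphs, list(validation[1]))
        else:
            val_batches = _chunked(graphs, list(y))

        state = {
            k: (np.zeros_like(p.data), np.zeros_like(p.data))
            for k, p in self.params_.items()
        }
        lr = train_cfg.learning_rate
        best_val = math.inf
        stale = 0
        step = 0
        log: list[dict] = []
        n = len(graphs)
        indices = np.arange(n)
        for epoch in range(train_cfg.epochs):
            rng.shuffle(indices)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, train_cfg.batch_size):
                sel = indices[start : start + train_cfg.batch_size]
                batch = _PackedBatch(
                    [graphs[i] for i in sel], [y[i] for i in sel]
                )
                P = _forward(self.params_, net_cfg, batch, True, rng)
                loss = _loss(P, batch)
                loss.backward()
                step += 1
                _adam_step(
                    self.params_, state, lr,
                    train_cfg.weight_decay, train_cfg.grad_clip_norm, step,
                )
                epoch_loss += float(loss.data)
                n_batches += 1
            train_loss = epoch_loss / max(n_batches, 1)
            val_num = val_den = 0.0
            for vb in val_batches:
                P = _forward(self.params_, net_cfg, vb, False, None)
                n_pairs = len(vb.gold_rows)
                val_num += float(_loss(P, vb).data) * n_pairs
                val_den += n_pairs
            val_loss = val_num / max(val_den, 1.0)
            # relative improvement threshold keeps numeric jitter from
            # triggering the plateau rule
            if val_loss < best_val * (1.0 - 1e-4):
                best_val = val_loss
                stale = 0
            else:
                stale += 1
                if stale > train_cfg.plateau_patience:
                    lr *= train_cfg.lr_decay_factor
                    stale = 0
            log.append(
                {
                    "epoch": epoch,
                    "train_loss": train_loss,
                    "val_loss": val_loss,
                    "lr": lr,
                    "seed": train_cfg.random_seed,
                }
            )
        self.training_log_ = log
        self.n_features_in_ = self.feature_config_.atom_dim
        return self

    # --- inference -------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("this AtomMapper instance is not fitted yet")

    def predict_proba(
        self, X: Sequence[ReactionRecord]
    ) -> list[MappingProbabilityMatrix]:
        """Per-reaction mapping probability matrices (inference mode)."""
        self._check_fitted()
        net_cfg = self._net_config()
        out = []
        for record in X:
            graphs = featurize(record, self.feature_config_)
            batch = _PackedBatch([graphs])
            P = _forward(self.params_, net_cfg, batch, False, None)
            out.append(
                MappingProbabilityMatrix(
                    P.data,
                    record.product_elements,
                    record.reactant_elements,
                )
            )
        return out

    def predict(self, X: Sequence[ReactionRecord]) -> list[AtomMapping]:
        return [
            decode_greedy(P, enforce_element_match=self.enforce_element_match)
            for P in self.predict_proba(X)
        ]

    def score(
        self, X: Sequence[ReactionRecord], y: Sequence[AtomMapping]
    ) -> float:
        """Fraction of reactions whose predicted map is CGR-equivalent to gold."""
        from .cgr import aam_equivalent

        preds = self.predict(X)
        ok = [
            aam_equivalent(pred, gold, rec)
            for rec, pred, gold in zip(X, preds, y)
        ]
        return sum(ok) / len(ok) if ok else float("nan")

    # --- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: weights + net config + feature schema."""
        self._check_fitted()
        meta = {
            "net": asdict(self._net_config()),
            "train": asdict(self._train_config()),
            "schema": self.feature_config_.schema_id(),
            "enforce_element_match": self.enforce_element_match,
        }
        arrays = {k: p.data for k, p in self.params_.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AtomMapper":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            arrays = {
                k: archive[k] for k in archive.files if k != "__meta__"
            }
        feature_config = FeatureConfig()
        if meta["schema"] != feature_config.schema_id():
            raise ValueError(
                "checkpoint feature schema does not match this version: "
                f"{meta['schema']} vs {feature_config.schema_id()}"
            )
        est = cls(
            enforce_element_match=meta.get("enforce_element_match", True),
            random_state=meta["train"]["random_seed"],
            **{
                k: meta["net"][k]
                for k in ("hidden_dim", "mpnn_layers", "attention_blocks",
                          "n_heads", "dropout")
            },
        )
        est.feature_config_ = feature_config
        est.params_ = {
            k: Tensor(v, requires_grad=True) for k, v in arrays.items()
        }
        est.training_log_ = []
        est.n_features_in_ = feature_config.atom_dim
        return est


def train_mapper(
    labeled: Sequence[tuple[ReactionRecord, AtomMapping]],
    net_cfg: Optional[MapperNetConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    validation: Optional[Sequence[tuple[ReactionRecord, AtomMapping]]] = None,
) -> AtomMapper:
    """Functional wrapper over :class:`AtomMapper` for config-driven training."""
    net_cfg = net_cfg or MapperNetConfig()
    train_cfg = train_cfg or TrainConfig()
    est = AtomMapper(
        hidden_dim=net_cfg.hidden_dim,
        mpnn_layers=net_cfg.mpnn_layers,
        attention_blocks=net_cfg.attention_blocks,
        n_heads=net_cfg.n_heads,
        dropout=net_cfg.dropout,
        epochs=train_cfg.epochs,
        batch_size=train_cfg.batch_size,
        learning_rate=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
        lr_decay_factor=train_cfg.lr_decay_factor,
        plateau_patience=train_cfg.plateau_patience,
        grad_clip_norm=train_cfg.grad_clip_norm,
        random_state=train_cfg.random_seed,
    )
    records = [r for r, _ in labeled]
    mappings = [m for _, m in labeled]
    val = None
    if validation:
        val = ([r for r, _ in validation], [m for _, m in validation])
    return est.fit(records, mappings, validation=val)
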