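"""Edge-level regression training with Adam and early stopping.

Training minimizes the sum-reduced squared error between predicted edge
scores and the ground-truth edge qualities z_ij, one minibatch of graphs
per optimizer step (gradients summed across the batch), shuffling graph
order each epoch. Mixed-quality minibatches keep the sigmoid regression
head out of its all-ones saturation regime, which single-graph steps on
label-skewed data fall into. The validation split is taken at the *target* level
(never the decoy level) so decoys of one complex never straddle the split.
Early stopping keeps the parameters from the best validation epoch and
halts after ``patience`` epochs without improvement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .gat_network import (GATConfig, GATGradients, GATParams, _sigmoid,
                          graph_index, loss_and_gradients, network_forward)

logger = logging.getLogger("ifaceqe")


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.0005
    max_epochs: int = 500
    patience: int = 40
    batch_size: int = 8
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

    @classmethod
    def from_yaml(cls, path: str) -> "TrainingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\n")
            for e, (tr, va) in enumerate(zip(self.train_loss, self.val_loss)):
                fh.write(f"{e}\t{tr:.6f}\t{va:.6f}\n")
            fh.write(f"# best_epoch={self.best_epoch}\t"
                     f"stop_reason={self.stop_reason}\n")


def edge_regression_loss(pred_scores: np.ndarray,
                         labels: np.ndarray) -> float:
    """Sum (not mean) of squared errors over the batch's edges."""
    pred_scores = np.asarray(pred_scores, float)
    labels = np.asarray(labels, float)
    if pred_scores.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {pred_scores.shape} vs {labels.shape}"
        )
    return float(((pred_scores - labels) ** 2).sum())


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to
    the gradient, matching the conventional optimizer configuration."""

    def __init__(self, params: GATParams, lr: float = 0.001,
                 weight_decay: float = 0.0005, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params.flat()]
        self.v = [np.zeros_like(p) for p in params.flat()]

    def step(self, grads: GATGradients) -> None:
        self.t += 1
        for k, (p, g) in enumerate(zip(self.params.flat(), grads.flat())):
            g = g + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def split_targets(target_ids: list[str], validation_fraction: float,
                  seed: int) -> tuple[list[str], list[str]]:
    """Deterministic target-level train/validation split (>=1 val target)."""
    uniq = sorted(set(target_ids))
    if len(uniq) < 2:
        raise ValueError("need >= 2 targets for a target-level split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(uniq))
    n_val = max(1, int(round(validation_fraction * len(uniq))))
    return order[n_val:], order[:n_val]


def _dataset_loss(graphs, params) -> float:
    """Mean per-edge squared error over a graph collection (forward only)."""
    total, n_edges = 0.0, 0
    for g in graphs:
        embeds, _ = network_forward(g.node_features, g.edge_features,
                                    graph_index(g), params)
        idx = np.asarray(g.edges)
        dots = (embeds[idx[:, 0]] * embeds[idx[:, 1]]).sum(axis=1)
        total += float(((_sigmoid(dots) - g.edge_label) ** 2).sum())
        n_edges += g.n_edges
    return total / max(n_edges, 1)


def train(decoy_graphs: dict[str, list], cfg: TrainingConfig,
          gat_config: GATConfig | None = None,
          val_targets: list[str] | None = None,
          ) -> tuple[GATParams, TrainingLog]:
    """Train on labeled graphs grouped by target id.

    Returns the parameters from the best-validation epoch. Fully
    reproducible from ``cfg.seed`` (which also seeds the Xavier
    initialization unless an explicit ``gat_config`` is given).
    """
    if val_targets is None:
        train_targets, val_targets = split_targets(
            list(decoy_graphs), cfg.validation_fraction, cfg.seed)
    else:
        train_targets = [t for t in decoy_graphs if t not in set(val_targets)]
    train_set = [g for t in train_targets for g in decoy_graphs[t]]
    val_set = [g for t in val_targets for g in decoy_graphs[t]]
    if not train_set or not val_set:
        raise ValueError("both train and validation splits must be non-empty")

    gat_config = gat_config or GATConfig(random_seed=cfg.seed)
    params = GATParams(gat_config)
    opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)

    log = TrainingLog()
    best_val = np.inf
    best_params = params.copy()
    epochs_since_best = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        # minibatches of graphs; the sum-reduced loss sums across the batch
        for k0 in range(0, len(order), cfg.batch_size):
            acc = None
            for idx in order[k0:k0 + cfg.batch_size]:
                loss, grads = loss_and_gradients(train_set[idx], params)
                epoch_loss += loss
                if acc is None:
                    acc = grads
                else:
                    for g_acc, g in zip(acc.flat(), grads.flat()):
                        g_acc += g
            opt.step(acc)
        val = _dataset_loss(val_set, params)
        if np.isnan(val):
            raise FloatingPointError(
                f"validation loss NaN at epoch {epoch}; log: {log}"
            )
        log.train_loss.append(epoch_loss / max(len(train_set), 1))
        log.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_params = params.copy()
            log.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                log.stop_reason = f"early stopping at epoch {epoch}"
                break
    else:
        log.stop_reason = f"reached max_epochs={cfg.max_epochs}"
    logger.info("training finished: %s (best epoch %d, val %.5f)",
                log.stop_reason, log.best_epoch, best_val)
    return best_params, log
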