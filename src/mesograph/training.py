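"""Training: dual-task pairwise ranking loss, cyclic LR, Adam loop.

Supervision is ordinal and bag-level only.  The sarcomatoid head is
trained to rank bags S > B > E (labels 2 > 1 > 0) and the epithelioid
head to rank E > B > S, with the pairwise hinge

    L = sum_i sum_j max(0, 1 - (Y_i - Y_j)(Z_i - Z_j))

summed over ordered pairs within a batch whose labels differ.  Each
head's own bag score (Z_s resp. Z_e) feeds its ranking loss; the
combined Z = Z_s - Z_e is used only for prediction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, Tensor, concat, relu
from .graphs import CoreGraph
from .model import ModelConfig, ModelParams, forward, forward_tensors, \
    init_params

__all__ = ["TrainConfig", "pairwise_ranking_loss", "ranking_loss_tensor",
           "dual_task_loss", "cyclic_lr", "train", "TrainResult"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule; defaults follow the published recipe."""

    lr_min: float = 2e-5
    lr_max: float = 1e-4
    cycle_length: int = 50
    cycle_decay: float = 0.8
    max_epochs: int = 500
    batch_size: int = 8
    patience: int = 50
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.lr_min <= self.lr_max:
            raise ValueError("need 0 < lr_min <= lr_max")
        if not 0 < self.cycle_decay <= 1:
            raise ValueError("cycle_decay must be in (0, 1]")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be below max_epochs")


def _pair_matrix(labels: np.ndarray) -> np.ndarray | None:
    """Signed incidence matrix of ordered pairs with differing labels."""
    n = len(labels)
    rows = []
    for i in range(n):
        for j in range(n):
            if i != j and labels[i] != labels[j]:
                row = np.zeros(n)
                s = float(labels[i] - labels[j])
                row[i] = s
                row[j] = -s
                rows.append(row)
    return np.asarray(rows) if rows else None


def pairwise_ranking_loss(bag_scores: np.ndarray,
                          labels: np.ndarray) -> float:
    """Hinge ranking loss over all ordered pairs with differing labels.

    Zero iff every pair is ranked in label order with margin >= 1, i.e.
    (Y_i - Y_j)(Z_i - Z_j) >= 1.  Equal-label pairs contribute a
    gradient-free constant in the printed formula and are excluded here.
    """
    labels = np.asarray(labels)
    if len(labels) < 2:
        raise ValueError("need at least two bags")
    if not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("ordinal labels must be in {0, 1, 2}")
    bag_scores = np.asarray(bag_scores, dtype=np.float64)
    pm = _pair_matrix(labels)
    if pm is None:
        return 0.0
    return float(np.maximum(0.0, 1.0 - pm @ bag_scores).sum())


def ranking_loss_tensor(bag_scores: list[Tensor],
                        labels: np.ndarray) -> Tensor:
    """Differentiable version over a list of (1, 1) bag-score tensors."""
    labels = np.asarray(labels)
    pm = _pair_matrix(labels)
    z = concat([t.reshape(1, 1) for t in bag_scores], axis=0)  # (n, 1)
    if pm is None:
        return (z * 0.0).sum()
    diffs = Tensor(pm) @ z
    return relu(1.0 - diffs).sum()


def dual_task_loss(z_s_bags: list[Tensor], z_e_bags: list[Tensor],
                   y_s: np.ndarray, y_e: np.ndarray) -> Tensor:
    """Sum of the two heads' ranking losses on their own bag scores."""
    y_s = np.asarray(y_s)
    y_e = np.asarray(y_e)
    if not np.all(y_s + y_e == 2):
        raise ValueError("task labels must satisfy y_s + y_e == 2")
    return (ranking_loss_tensor(z_s_bags, y_s)
            + ranking_loss_tensor(z_e_bags, y_e))


def cyclic_lr(epoch: int, config: TrainConfig) -> float:
    """Decaying triangular learning-rate wave.

    Each cycle starts at ``lr_min``, peaks mid-cycle at
    ``lr_min + decay^c * (lr_max - lr_min)`` and returns to ``lr_min``.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    cycle, pos = divmod(epoch, config.cycle_length)
    peak = config.lr_min + (config.cycle_decay ** cycle
                            * (config.lr_max - config.lr_min))
    half = config.cycle_length / 2.0
    frac = pos / half if pos <= half else (config.cycle_length - pos) / half
    return config.lr_min + frac * (peak - config.lr_min)


@dataclass
class TrainResult:
    params: ModelParams
    history: pd.DataFrame
    best_epoch: int
    best_val_auroc: float
    train_ids: list[str] = field(default_factory=list)
    val_ids: list[str] = field(default_factory=list)


def _val_auroc(graphs: list[CoreGraph], params: ModelParams) -> float:
    """Bag AUROC with B and S as the positive class against E."""
    z = np.array([forward(g, params).Z for g in graphs])
    y = np.array([1 if g.y_s_task > 0 else 0 for g in graphs])
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, z))


def _val_loss(graphs: list[CoreGraph], params: ModelParams) -> float:
    """Dual ranking loss over the whole validation set."""
    z_s = np.array([forward(g, params).Z_s for g in graphs])
    z_e = np.array([forward(g, params).Z_e for g in graphs])
    y_s = np.array([g.y_s_task for g in graphs])
    if len(np.unique(y_s)) < 2:
        return float("nan")
    return (pairwise_ranking_loss(z_s, y_s)
            + pairwise_ranking_loss(z_e, 2 - y_s))


def _stratified_split(graphs: list[CoreGraph], val_fraction: float,
                      rng: np.random.Generator
                      ) -> tuple[list[CoreGraph], list[CoreGraph]]:
    """75/25 split stratified by subtype so both splits see every class."""
    train, val = [], []
    by_label: dict[int, list[CoreGraph]] = {}
    for g in graphs:
        by_label.setdefault(g.y_s_task, []).append(g)
    for label in sorted(by_label):
        group = by_label[label]
        order = rng.permutation(len(group))
        n_val = max(1, int(round(val_fraction * len(group)))) \
            if len(group) > 1 else 0
        for pos, idx in enumerate(order):
            (val if pos < n_val else train).append(group[idx])
    return train, val


def train(graphs: list[CoreGraph], model_config: ModelConfig,
          config: TrainConfig | None = None) -> TrainResult:
    """Fit the network on bag-labelled core graphs.

    The cores are split 75/25 into train and validation sets (stratified
    by subtype); training minimises the dual ranking loss with Adam under
    the decaying cyclic learning rate, and the checkpoint with the best
    validation AUROC (B+S vs E) is returned.  Fully reproducible given
    ``config.seed``.
    """
    config = config or TrainConfig()
    if len(graphs) < 2:
        raise ValueError("need at least two bags to train")
    rng = np.random.default_rng(config.seed)
    train_graphs, val_graphs = _stratified_split(
        graphs, config.val_fraction, rng)
    if not train_graphs:
        raise ValueError("empty training split")

    params = init_params(model_config, seed=int(rng.integers(2**31 - 1)),
                         feature_names=train_graphs[0].feature_names)
    optimizer = Adam(params.tensors(), lr=config.lr_min)

    best = copy.deepcopy(params)
    best_auroc = -np.inf
    best_val_loss = np.inf
    best_epoch = -1
    rows = []
    since_best = 0
    for epoch in range(config.max_epochs):
        lr = cyclic_lr(epoch, config)
        optimizer.lr = lr
        order = rng.permutation(len(train_graphs))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [train_graphs[i] for i in order[start:start
                                                    + config.batch_size]]
            if len(batch) < 2:
                continue
            z_s_bags, z_e_bags = [], []
            for g in batch:
                z_s, z_e = forward_tensors(g, params)
                z_s_bags.append(z_s.mean())
                z_e_bags.append(z_e.mean())
            loss = dual_task_loss(
                z_s_bags, z_e_bags,
                np.array([g.y_s_task for g in batch]),
                np.array([g.y_e_task for g in batch]))
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
        val_auroc = _val_auroc(val_graphs, params) if val_graphs else \
            float("nan")
        val_loss = _val_loss(val_graphs, params) if val_graphs else \
            float("nan")
        rows.append({"epoch": epoch, "loss": epoch_loss, "lr": lr,
                     "val_auroc": val_auroc, "val_loss": val_loss})
        # best checkpoint by validation AUROC; ties (common once the
        # ranking is already perfect) broken by validation ranking loss
        # so margins keep improving
        improved = np.isfinite(val_auroc) and (
            val_auroc > best_auroc
            or (val_auroc == best_auroc and val_loss < best_val_loss))
        if improved:
            best_auroc = val_auroc
            best_val_loss = val_loss
            best = copy.deepcopy(params)
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if val_graphs and since_best > config.patience:
                break
    if best_epoch < 0:  # no usable validation signal: keep final params
        best, best_epoch, best_auroc = params, len(rows) - 1, float("nan")
    return TrainResult(
        params=best,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_auroc=float(best_auroc),
        train_ids=[g.core_id for g in train_graphs],
        val_ids=[g.core_id for g in val_graphs],
    )
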