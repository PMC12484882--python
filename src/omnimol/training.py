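"""Losses, the task-balancing sampler, and the desk-scale training loop.

Loss design
-----------
* ``forcefield_loss`` — L1 between the final geometry update P^S − P^{S−1}
  and the remaining displacement to equilibrium P* − P^{S−1}; the reference
  state cancels algebraically, so the value equals mean |P^S − P*|.
* ``regression_loss`` — mean absolute error on the z-scored target scale.
* ``classification_loss`` — binary cross-entropy reweighted by the training
  positive ratio t₊: positives weighted 1/(2t₊), negatives 1/(2(1−t₊)), so
  the expected weight mass of each class is 1/2 and at t₊ = 0.5 the loss is
  exactly standard BCE.
* ``total_loss`` — L_reg + γ·L_cls; the geometry term enters the training
  objective with its own coefficient λ_geo.

The sampler adjusts per-task batch frequencies to S̃_i = (1−θ)S_i + θS̄,
interpolating between proportional (θ=0) and uniform (θ=1) task sampling
while conserving the total sample budget.

The geometry pathway is supervised at the edge level: the final block's
predicted magnitudes m_ij are matched (L1) against the decomposed labels
u_ij = d_ij·(P* − P^{S−1})_i, evaluated in the geometry of state S−1.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from ._autodiff import Tensor
from .drlabel import decompose_labels
from .model import ModelOutput, OmniMolModel
from .molgraph import Conformation, perturb_conformation
from .nn import Adam
from .tmoe import TaskMeta

logger = logging.getLogger(__name__)

__all__ = ["LossBundle", "PropertyHypergraph", "MultiTaskDataset", "TrainConfig",
           "forcefield_loss", "zscore", "inverse_zscore", "regression_loss",
           "classification_loss", "total_loss", "balanced_batch_sizes",
           "TaskBalancedSampler", "train", "evaluate", "geometry_loss"]

_P_CLAMP = 1e-7


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def forcefield_loss(P_S, P_S_minus_1, P_star):
    """Mean absolute deviation of the final update from the required update.

    Algebraically identical to mean |P^S − P*| for any reference P^{S−1}.
    """
    P_S, P_S_minus_1, P_star = _lift(P_S), _lift(P_S_minus_1), _lift(P_star)
    if not (P_S.shape == P_S_minus_1.shape == P_star.shape):
        raise ValueError(f"shape mismatch: {P_S.shape}, {P_S_minus_1.shape}, {P_star.shape}")
    return ((P_S - P_S_minus_1) - (P_star - P_S_minus_1)).abs().mean()


def zscore(y, mu_reg: float, sigma_reg: float):
    if sigma_reg <= 0:
        raise ValueError("sigma_reg must be positive")
    return (_lift(y) - mu_reg) / sigma_reg


def inverse_zscore(y_norm, mu_reg: float, sigma_reg: float):
    if sigma_reg <= 0:
        raise ValueError("sigma_reg must be positive")
    return _lift(y_norm) * sigma_reg + mu_reg


def regression_loss(y_norm, p):
    return (_lift(y_norm) - _lift(p)).abs().mean()


def classification_loss(y, p, t_plus: float):
    if not 0.0 < t_plus < 1.0:
        raise ValueError(f"t_plus must be in (0, 1), got {t_plus}")
    y, p = _lift(y), _lift(p)
    p = p.clip(_P_CLAMP, 1.0 - _P_CLAMP)
    pos = y * (1.0 / (2.0 * t_plus)) * p.log()
    neg = (1.0 - y) * (1.0 / (2.0 * (1.0 - t_plus))) * (1.0 - p).log()
    return -(pos + neg).mean()


def total_loss(l_reg, l_cls, gamma: float):
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return _lift(l_reg) + gamma * _lift(l_cls)


@dataclass
class LossBundle:
    loss_forcefield: float
    loss_reg: float
    loss_cls: float
    gamma: float
    loss_total: float = field(init=False)

    def __post_init__(self):
        self.loss_total = self.loss_reg + self.gamma * self.loss_cls


def balanced_batch_sizes(sizes, theta: float) -> np.ndarray:
    """Adjusted per-task sizes S̃_i = (1−θ)S_i + θS̄; Σ S̃ = Σ S identically."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    sizes = np.asarray(sizes, dtype=np.float64)
    return (1.0 - theta) * sizes + theta * sizes.mean()


class TaskBalancedSampler:
    """Draws task indices with probabilities proportional to adjusted sizes."""

    def __init__(self, sizes, theta: float, rng: np.random.Generator):
        self.adjusted = balanced_batch_sizes(sizes, theta)
        self.probs = self.adjusted / self.adjusted.sum()
        self.rng = rng

    def draw(self) -> int:
        return int(self.rng.choice(len(self.probs), p=self.probs))


@dataclass
class PropertyHypergraph:
    """Molecules as nodes, properties as hyperedges over their labeled subsets."""
    molecules: list
    properties: list
    membership: dict  # task_id -> set of molecule indices

    def __post_init__(self):
        universe = set(range(len(self.molecules)))
        for tid, members in self.membership.items():
            if not set(members) <= universe:
                raise ValueError(f"membership of property {tid} outside molecule set")

    def labeled_fraction(self, task_id) -> float:
        return len(self.membership[task_id]) / len(self.molecules)


@dataclass
class MultiTaskDataset:
    """Conformations plus partially-annotated per-task labels."""
    molecules: list                 # Conformation objects
    tasks: list                     # TaskMeta objects
    labels: dict                    # task_id -> {mol_index: value}

    @property
    def hypergraph(self) -> PropertyHypergraph:
        return PropertyHypergraph(
            molecules=self.molecules, properties=[t.task_id for t in self.tasks],
            membership={tid: set(lab) for tid, lab in self.labels.items()})

    def task_by_id(self, task_id: int) -> TaskMeta:
        for t in self.tasks:
            if t.task_id == task_id:
                return t
        raise KeyError(task_id)


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 16
    gamma: float = 1.0        # classification weight in the total loss
    theta: float = 0.5        # task-balancing factor
    lambda_geo: float = 1.0   # geometry-loss coefficient
    seed: int = 0
    resample_sigma: float | None = None  # fresh perturbation per draw, if set
    supervise_all_blocks: bool = False   # per-block geometry supervision (off: final only)
    early_stop_train_acc: float | None = None
    early_stop_patience: int = 2


def geometry_loss(out: ModelOutput, P_star: np.ndarray,
                  supervise_all_blocks: bool = False) -> Tensor:
    """Edge-level L1 between predicted magnitudes and decomposed labels."""
    blocks = range(len(out.m_tensors)) if supervise_all_blocks else [len(out.m_tensors) - 1]
    loss = None
    for x in blocks:
        graph = out.block_graphs[x]           # geometry of state x (= S−1 for last)
        u = decompose_labels(P_star - out.trajectory[x], graph)
        term = (out.m_tensors[x] - Tensor(u)).abs().mean()
        loss = term if loss is None else loss + term
    return loss * (1.0 / len(list(blocks)))


def _roc_auc(y: np.ndarray, p: np.ndarray) -> float:
    pos, neg = int(y.sum()), int((1 - y).sum())
    if pos == 0 or neg == 0:
        return float("nan")
    ranks = rankdata(p)
    return (ranks[y == 1].sum() - pos * (pos + 1) / 2) / (pos * neg)


def evaluate(model: OmniMolModel, dataset: MultiTaskDataset,
             task_ids=None, indices=None) -> dict:
    """Per-task metrics (accuracy/AUC for classification, MAE/R² for regression)."""
    metrics = {}
    task_ids = task_ids if task_ids is not None else [t.task_id for t in dataset.tasks]
    for tid in task_ids:
        meta = dataset.task_by_id(tid)
        lab = dataset.labels.get(tid, {})
        idx = sorted(lab) if indices is None else [i for i in indices if i in lab]
        if not idx:
            continue
        y = np.array([lab[i] for i in idx], dtype=np.float64)
        p = np.array([model(dataset.molecules[i], meta).prediction for i in idx])
        if meta.task_type == "classification":
            metrics[tid] = {"accuracy": float(((p >= 0.5) == (y >= 0.5)).mean()),
                            "auc": _roc_auc(y, p), "n": len(idx)}
        else:
            y_norm = (y - meta.target_mean) / meta.target_std
            ss_res = float(((y_norm - p) ** 2).sum())
            ss_tot = float(((y_norm - y_norm.mean()) ** 2).sum())
            metrics[tid] = {"mae": float(np.abs(y_norm - p).mean()),
                            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
                            "n": len(idx)}
    return metrics


def _molecule_losses(model: OmniMolModel, conf: Conformation, meta: TaskMeta,
                     label: float | None, cfg: TrainConfig, rng: np.random.Generator):
    """Forward one molecule; returns (loss tensor or None, stats dict)."""
    if cfg.resample_sigma is not None and conf.equilibrium_positions is not None:
        conf = perturb_conformation(conf, cfg.resample_sigma, rng)
    out = model(conf, meta)
    terms, stats = [], {}
    if label is not None:
        if meta.task_type == "classification":
            l_cls = classification_loss(np.float64(label), out.prediction_tensor,
                                        meta.positive_ratio)
            terms.append(total_loss(Tensor(0.0), l_cls, cfg.gamma))
            stats["cls_loss"] = l_cls.item()
            stats["correct"] = float((out.prediction >= 0.5) == (label >= 0.5))
        else:
            y_norm = zscore(np.float64(label), meta.target_mean, meta.target_std)
            l_reg = regression_loss(y_norm, out.prediction_tensor)
            terms.append(total_loss(l_reg, Tensor(0.0), cfg.gamma))
            stats["reg_loss"] = l_reg.item()
    if conf.equilibrium_positions is not None and cfg.lambda_geo > 0:
        l_geo = geometry_loss(out, conf.equilibrium_positions, cfg.supervise_all_blocks)
        terms.append(cfg.lambda_geo * l_geo)
        stats["geo_loss"] = l_geo.item()
        stats["ff_loss"] = forcefield_loss(
            out.trajectory[-1], out.trajectory[-2], conf.equilibrium_positions).item()
    if not terms:
        return None, stats
    loss = terms[0]
    for t in terms[1:]:
        loss = loss + t
    return loss, stats


def train(model: OmniMolModel, dataset: MultiTaskDataset, cfg: TrainConfig,
          checkpoint_path=None, resume_state=None):
    """Task-balanced multi-task training.

    Each optimizer step draws one task (frequency ∝ adjusted size), then a
    batch of molecules labeled for it; gradients are averaged over the batch.
    Tasks without labeled molecules fall back to geometry-only supervision
    over all molecules when equilibria are available, otherwise are skipped
    with a warning. Returns (metrics log, trainer state) and optionally
    pickles the state for bit-identical resumption.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    start_epoch = 0
    metrics_log: list[dict] = []
    if resume_state is not None:
        model.load_state_dict(resume_state["model"])
        opt.load_state_dict(resume_state["optimizer"])
        rng.bit_generator.state = resume_state["rng"]
        start_epoch = resume_state["epoch"]
        metrics_log = list(resume_state["metrics_log"])

    labeled_tasks = [t for t in dataset.tasks if dataset.labels.get(t.task_id)]
    for t in dataset.tasks:
        if not dataset.labels.get(t.task_id):
            logger.warning("task %s has no labeled molecules; skipped from sampling",
                           t.task_id)
    geometry_only = not labeled_tasks
    if geometry_only:
        if not dataset.tasks:
            raise ValueError("dataset has no tasks")
        pools = {dataset.tasks[0].task_id: np.arange(len(dataset.molecules))}
        sampler_tasks = [dataset.tasks[0]]
        sizes = [len(dataset.molecules)]
    else:
        pools = {t.task_id: np.array(sorted(dataset.labels[t.task_id]))
                 for t in labeled_tasks}
        sampler_tasks = labeled_tasks
        sizes = [len(pools[t.task_id]) for t in labeled_tasks]
    sampler = TaskBalancedSampler(sizes, cfg.theta, rng)
    steps_per_epoch = max(1, int(np.ceil(sum(sizes) / cfg.batch_size)))

    streak = 0
    epoch = start_epoch - 1
    for epoch in range(start_epoch, cfg.epochs):
        agg: dict[str, list] = {}
        for _ in range(steps_per_epoch):
            meta = sampler_tasks[sampler.draw()]
            pool = pools[meta.task_id]
            batch = rng.choice(pool, size=min(cfg.batch_size, len(pool)), replace=False)
            opt.zero_grad()
            n_terms = 0
            for i in batch:
                label = (None if geometry_only
                         else dataset.labels[meta.task_id].get(int(i)))
                loss, stats = _molecule_losses(model, dataset.molecules[int(i)], meta,
                                               label, cfg, rng)
                for k, v in stats.items():
                    agg.setdefault(k, []).append(v)
                if loss is not None:
                    loss.backward()
                    n_terms += 1
            if n_terms:
                for p in model.parameters():
                    if p.grad is not None:
                        p.grad /= n_terms
                opt.step()
        row = {"epoch": epoch}
        row.update({k: float(np.mean(v)) for k, v in agg.items()})
        metrics_log.append(row)
        logger.info("epoch %d: %s", epoch,
                    " ".join(f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
        if cfg.early_stop_train_acc is not None and "correct" in row:
            streak = streak + 1 if row["correct"] >= cfg.early_stop_train_acc else 0
            if streak >= cfg.early_stop_patience:
                logger.info("early stop at epoch %d (train accuracy target held)", epoch)
                break

    state = {"model": model.state_dict(), "optimizer": opt.state_dict(),
             "rng": rng.bit_generator.state, "epoch": epoch + 1,
             "metrics_log": metrics_log}
    if checkpoint_path is not None:
        Path(checkpoint_path).write_bytes(pickle.dumps(state))
    return metrics_log, state
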