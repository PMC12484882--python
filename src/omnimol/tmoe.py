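"""Task meta-information encoding, routing, and the t-MoE layer.

Each prediction task carries meta-information (index, endpoint group,
task type, and label statistics — positive ratio η for classification,
mean/std for regression). A learned encoder turns this into a task
embedding; a router maps the embedding to softmax gating weights α over
N_M expert feed-forward networks; the MoE output is the dense convex
combination Σ_i α_i·FFN_i(X) — no top-k sparsification, so the model
navigates the full convex hull of expert outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from ._autodiff import Tensor, concat

__all__ = ["TaskMeta", "TASK_GROUPS", "TaskMetaEncoder", "Router", "MoE",
           "moe_forward", "load_task_meta_csv", "save_task_embeddings_csv"]

TASK_GROUPS = ("absorption", "distribution", "metabolism", "excretion",
               "toxicity", "physicochemical", "other")
TASK_TYPES = ("classification", "regression")


@dataclass(frozen=True)
class TaskMeta:
    """Meta-information for one prediction task.

    Classification tasks carry the training-set positive ratio η (which also
    serves as the loss reweighting ratio t₊); regression tasks carry the
    training-target mean μ and std σ.
    """

    task_id: int
    task_type: str
    group: str = "other"
    name: str = ""
    positive_ratio: float | None = None
    target_mean: float | None = None
    target_std: float | None = None

    def __post_init__(self):
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"task_type must be one of {TASK_TYPES}, got {self.task_type!r}")
        if self.group not in TASK_GROUPS:
            raise ValueError(f"group must be one of {TASK_GROUPS}, got {self.group!r}")
        if self.task_type == "classification":
            if self.positive_ratio is None or not (0.0 < self.positive_ratio < 1.0):
                raise ValueError("classification task needs positive_ratio in (0, 1)")
            if self.target_mean is not None or self.target_std is not None:
                raise ValueError("classification task must not carry mean/std")
        else:
            if self.target_mean is None or self.target_std is None:
                raise ValueError("regression task needs target_mean and target_std")
            if self.target_std <= 0:
                raise ValueError("target_std must be positive")
            if self.positive_ratio is not None:
                raise ValueError("regression task must not carry positive_ratio")


class TaskMetaEncoder(nn.Module):
    """t_meta → t_emb.

    Numeric encoding: [one-hot group ‖ one-hot type ‖ learned id-embedding ‖
    (η, μ, σ) with absent fields zero-filled], passed through a two-layer MLP.
    """

    N_STATS = 3

    def __init__(self, d_emb: int, rng: np.random.Generator, max_tasks: int = 256,
                 d_id: int = 16):
        super().__init__()
        self.d_emb = d_emb
        self.max_tasks = max_tasks
        self.id_embedding = nn.Embedding(max_tasks, d_id, rng)
        d_meta = len(TASK_GROUPS) + len(TASK_TYPES) + d_id + self.N_STATS
        self.mlp = nn.FFN(d_meta, d_emb, d_emb, rng)

    def meta_vector(self, meta: TaskMeta) -> np.ndarray:
        """The fixed (non-learned) part of the numeric encoding."""
        group = np.zeros(len(TASK_GROUPS))
        group[TASK_GROUPS.index(meta.group)] = 1.0
        ttype = np.zeros(len(TASK_TYPES))
        ttype[TASK_TYPES.index(meta.task_type)] = 1.0
        stats = np.array([meta.positive_ratio or 0.0, meta.target_mean or 0.0,
                          meta.target_std or 0.0])
        return np.concatenate([group, ttype, stats])

    def forward(self, meta: TaskMeta) -> Tensor:
        if not 0 <= meta.task_id < self.max_tasks:
            raise ValueError(f"task_id {meta.task_id} outside [0, {self.max_tasks})")
        fixed = self.meta_vector(meta)
        idv = self.id_embedding(np.array([meta.task_id])).reshape(-1)
        parts = concat([Tensor(fixed[:len(TASK_GROUPS) + len(TASK_TYPES)]), idv,
                        Tensor(fixed[len(TASK_GROUPS) + len(TASK_TYPES):])], axis=0)
        return self.mlp(parts)


class Router(nn.Module):
    """t_emb → gating weights α on the N_M-simplex."""

    def __init__(self, d_emb: int, n_experts: int, rng: np.random.Generator):
        super().__init__()
        if n_experts < 1:
            raise ValueError(f"need at least one expert, got {n_experts}")
        self.n_experts = n_experts
        self.linear = nn.Linear(d_emb, n_experts, rng)

    def forward(self, t_emb: Tensor) -> Tensor:
        return self.linear(t_emb).softmax(axis=-1)


def moe_forward(X: Tensor, alpha: Tensor, experts: list[nn.Module]) -> Tensor:
    """Dense mixture X' = Σ_i α_i · FFN_i(X), applied row-wise over nodes."""
    n_alpha = alpha.shape[-1]
    if n_alpha != len(experts):
        raise ValueError(f"{len(experts)} experts but alpha has length {n_alpha}")
    out = alpha[0] * experts[0](X)
    for i in range(1, len(experts)):
        out = out + alpha[i] * experts[i](X)
    return out


class MoE(nn.Module):
    def __init__(self, dim: int, n_experts: int, rng: np.random.Generator,
                 hidden_mult: int = 2):
        super().__init__()
        self.experts = [nn.FFN(dim, hidden_mult * dim, dim, rng) for _ in range(n_experts)]

    def forward(self, X: Tensor, alpha: Tensor) -> Tensor:
        return moe_forward(X, alpha, self.experts)


def load_task_meta_csv(path) -> list[TaskMeta]:
    """Read a task meta table (task_id, name, type, group, positive_ratio, mean, std)."""
    df = pd.read_csv(path)
    metas = []
    for _, row in df.iterrows():
        ttype = str(row["type"])
        is_cls = ttype == "classification"
        metas.append(TaskMeta(
            task_id=int(row["task_id"]), task_type=ttype,
            group=str(row.get("group", "other")), name=str(row.get("name", "")),
            positive_ratio=float(row["positive_ratio"]) if is_cls else None,
            target_mean=None if is_cls else float(row["mean"]),
            target_std=None if is_cls else float(row["std"])))
    return metas


def save_task_embeddings_csv(path, encoder: TaskMetaEncoder,
                             metas: list[TaskMeta]) -> None:
    """Dump learned t_emb vectors for external 2-D projection/visualization."""
    rows = {m.name or str(m.task_id): encoder(m).data for m in metas}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"e{i}" for i in range(encoder.d_emb)])
    df.index.name = "task"
    df.to_csv(path)
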