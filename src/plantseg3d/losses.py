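"""Training objective: semantic cross-entropy, discriminative instance loss,
and a pairwise double-hinge loss on the fused mid-level features.

The instance loss follows the discriminative-embedding formulation: a *pull*
term L_s drawing every point within a margin ``delta_s`` of its instance
center, a *push* term L_d forcing instance centers at least ``2 * delta_d``
apart, and a regularizer L_reg keeping centers near the origin:

    L_s   = (1/I) Σ_i (1/N_i) Σ_j max(0, ||c_i - f_j|| - δ_s)²
    L_d   = (1/I²) Σ_{iA} Σ_{iB≠iA} max(0, 2δ_d - ||c_iA - c_iB||)²
    L_reg = (1/I) Σ_i ||c_i||
    L_ins = α L_s + β L_d + γ L_reg

The double-hinge loss acts on sampled point pairs of the fused map: pairs of
the same instance are pulled together (their distance contributes directly),
pairs of the same semantic class but different instances are pushed beyond a
margin, and pairs of different classes beyond a larger margin.

The total objective is ``L = L_sem + L_ins + L_DHL``.  All terms are
non-negative, and L_s/L_d are invariant under a common translation of the
embedding (L_reg deliberately is not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "LossParams", "semantic_loss", "pull_loss", "push_loss", "reg_loss",
    "instance_loss", "double_hinge_loss", "total_loss", "instance_centers",
]

_EPS_LOG = 1e-12
_EPS_NORM = 1e-12


@dataclass
class LossParams:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.001
    delta_s: float = 0.5
    delta_d: float = 1.5
    dhl_margins: tuple[float, float] = (1.0, 2.0)
    dhl_max_points: int = 64
    sem_reduction: str = "mean"   # "mean" for training, "sum" for the printed form

    def __post_init__(self) -> None:
        if not self.delta_d > self.delta_s > 0:
            raise ValueError("need delta_d > delta_s > 0")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.sem_reduction not in ("mean", "sum"):
            raise ValueError("sem_reduction must be 'mean' or 'sum'")


def _row_norms(x: Tensor) -> Tensor:
    return ((x**2).sum(axis=-1) + _EPS_NORM).sqrt()


def instance_centers(embeddings: Tensor, ins_gt: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Per-instance embedding means via an indicator matmul (differentiable).

    Returns (centers: I x D tensor, instance ids in center order).
    """
    embeddings = as_tensor(embeddings)
    ins_gt = np.asarray(ins_gt)
    ids = np.unique(ins_gt)
    ind = (ins_gt[None, :] == ids[:, None]).astype(np.float64)   # I x N
    counts = ind.sum(axis=1, keepdims=True)
    centers = Tensor(ind / counts) @ embeddings
    return centers, ids


def semantic_loss(probs, gt: np.ndarray, n_classes: int | None = None,
                  reduction: str = "mean") -> Tensor:
    """Cross-entropy ``-Σ_i Σ_j x'_j(i) log x_j(i)`` on per-point class probabilities.

    ``probs`` rows must sum to one (post-softmax); the log is clamped at 1e-12
    so a zero probability at the true class never produces a NaN.  ``gt`` may
    be integer ids or a one-hot matrix.
    """
    probs = as_tensor(probs)
    n, c = probs.shape
    gt = np.asarray(gt)
    if gt.ndim == 2:   # one-hot
        onehot = gt.astype(np.float64)
    else:
        if gt.min() < 0 or gt.max() >= c:
            raise ValueError("semantic ids out of range")
        onehot = np.zeros((n, c))
        onehot[np.arange(n), gt] = 1.0
    logp = probs.clip_min(_EPS_LOG).log()
    total = -(Tensor(onehot) * logp).sum()
    return total / n if reduction == "mean" else total


def pull_loss(embeddings, ins_gt: np.ndarray, delta_s: float = 0.5) -> Tensor:
    """L_s: hinged squared distance of each point to its instance center."""
    embeddings = as_tensor(embeddings)
    ins_gt = np.asarray(ins_gt)
    if ins_gt.size == 0 or len(np.unique(ins_gt)) == 0:
        warnings.warn("pull_loss called with no instances; returning 0")
        return Tensor(0.0)
    centers, ids = instance_centers(embeddings, ins_gt)
    loss = Tensor(0.0)
    for i, ins in enumerate(ids):
        member = np.flatnonzero(ins_gt == ins)
        diff = embeddings.take(member) - centers.take(np.full(len(member), i))
        hinge = (_row_norms(diff) - delta_s).relu()
        loss = loss + (hinge**2).mean()
    return loss / len(ids)


def push_loss(centers, delta_d: float = 1.5) -> Tensor:
    """L_d: hinged squared margin between all ordered pairs of instance centers."""
    centers = as_tensor(centers)
    n = centers.shape[0]
    if n <= 1:
        return Tensor(0.0)
    ia, ib = np.nonzero(~np.eye(n, dtype=bool))
    diff = centers.take(ia) - centers.take(ib)
    hinge = (2.0 * delta_d - _row_norms(diff)).relu()
    return (hinge**2).sum() / n**2


def reg_loss(centers) -> Tensor:
    """L_reg: mean center norm, pulling the embedding toward the origin."""
    centers = as_tensor(centers)
    return _row_norms(centers).mean()


def instance_loss(embeddings, ins_gt: np.ndarray, params: LossParams | None = None):
    """L_ins = α L_s + β L_d + γ L_reg; returns (L_ins, components dict)."""
    params = params or LossParams()
    embeddings = as_tensor(embeddings)
    l_s = pull_loss(embeddings, ins_gt, params.delta_s)
    centers, _ = instance_centers(embeddings, ins_gt)
    l_d = push_loss(centers, params.delta_d)
    l_r = reg_loss(centers)
    total = params.alpha * l_s + params.beta * l_d + params.gamma * l_r
    return total, {"L_s": l_s, "L_d": l_d, "L_reg": l_r}


def _pair_indices(n: int, max_points: int, rng: np.random.Generator | None):
    if n > max_points:
        rng = rng or np.random.default_rng(0)
        keep = rng.choice(n, size=max_points, replace=False)
    else:
        keep = np.arange(n)
    ii, jj = np.triu_indices(len(keep), k=1)
    return keep[ii], keep[jj]


def double_hinge_loss(fused, sem_gt: np.ndarray, ins_gt: np.ndarray,
                      margins: tuple[float, float] = (1.0, 2.0),
                      max_points: int = 64,
                      rng: np.random.Generator | None = None) -> Tensor:
    """Three-regime pairwise hinge on the fused features, mean over pairs.

    same instance            -> d_ij
    same class, diff instance-> max(0, m_same - d_ij)
    different class          -> max(0, m_diff - d_ij)

    At most ``max_points`` points are sampled per call (all unordered pairs of
    the sample), keeping the cost bounded per cloud per step.
    """
    fused = as_tensor(fused)
    sem_gt, ins_gt = np.asarray(sem_gt), np.asarray(ins_gt)
    n = fused.shape[0]
    if n < 2:
        return Tensor(0.0)
    ii, jj = _pair_indices(n, max_points, rng)
    d = _row_norms(fused.take(ii) - fused.take(jj))
    same_ins = ins_gt[ii] == ins_gt[jj]
    same_sem = sem_gt[ii] == sem_gt[jj]
    m_same, m_diff = margins
    w_pull = same_ins.astype(np.float64)
    w_same = (same_sem & ~same_ins).astype(np.float64)
    w_diff = (~same_sem).astype(np.float64)
    loss = (Tensor(w_pull) * d
            + Tensor(w_same) * (m_same - d).relu()
            + Tensor(w_diff) * (m_diff - d).relu())
    return loss.mean()


def total_loss(outputs, sem_gt: np.ndarray, ins_gt: np.ndarray,
               params: LossParams | None = None,
               rng: np.random.Generator | None = None):
    """L = L_sem + L_ins + L_DHL on one cloud's network outputs.

    ``outputs`` is an EmbeddingOutput; returns (L, components dict) where the
    components are plain floats summing to L.
    """
    from .autodiff import softmax

    params = params or LossParams()
    probs = softmax(outputs.sem_logits, axis=-1)
    l_sem = semantic_loss(probs, sem_gt, reduction=params.sem_reduction)
    l_ins, parts = instance_loss(outputs.ins_embed, ins_gt, params)
    l_dhl = double_hinge_loss(outputs.fused, sem_gt, ins_gt,
                              margins=params.dhl_margins,
                              max_points=params.dhl_max_points, rng=rng)
    total = l_sem + l_ins + l_dhl
    log = {"L": total.item(), "L_sem": l_sem.item(), "L_ins": l_ins.item(),
           "L_s": parts["L_s"].item(), "L_d": parts["L_d"].item(),
           "L_reg": parts["L_reg"].item(), "L_DHL": l_dhl.item()}
    return total, log
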