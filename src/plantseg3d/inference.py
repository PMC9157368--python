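"""From network outputs to discrete labelings.

Semantics are the row-wise argmax of the class logits.  Instances come from
flat-kernel mean-shift in the learned embedding space: every point seeds a
mode, seeds are iterated to convergence, modes closer than ``bandwidth / 2``
are merged, clusters below a minimum size are reassigned to the nearest
surviving mode, and ids are relabeled contiguously by decreasing cluster
size.  The procedure is fully deterministic — there is no random mode
seeding — so repeated runs agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SegmentationResult", "predict_semantics", "mean_shift_modes",
    "cluster_instances", "assign_instance_class", "segment_cloud",
    "default_min_cluster_size",
]


@dataclass
class SegmentationResult:
    sem_pred: np.ndarray          # N class ids
    ins_pred: np.ndarray          # N instance ids, contiguous from 0
    ins_class: dict[int, int]     # instance id -> majority semantic id

    def __post_init__(self) -> None:
        if self.sem_pred.shape != self.ins_pred.shape:
            raise ValueError("semantic and instance labelings must cover the same points")


def predict_semantics(sem_logits: np.ndarray) -> np.ndarray:
    """Row-wise argmax; ties resolve to the lowest class id."""
    logits = np.asarray(sem_logits)
    return np.argmax(logits, axis=1)


def default_min_cluster_size(n_points: int) -> int:
    return max(10, n_points // 500)


def mean_shift_modes(x: np.ndarray, bandwidth: float, tol: float = 1e-4,
                     max_iter: int = 300) -> np.ndarray:
    """Flat-kernel mean-shift from every point; returns one mode per point."""
    x = np.asarray(x, dtype=np.float64)
    tree = cKDTree(x)
    modes = x.copy()
    active = np.arange(len(x))
    for _ in range(max_iter):
        if len(active) == 0:
            break
        neighbors = tree.query_ball_point(modes[active], r=bandwidth)
        new = np.array([x[nb].mean(axis=0) if nb else modes[a]
                        for a, nb in zip(active, neighbors)])
        shift = np.linalg.norm(new - modes[active], axis=1)
        modes[active] = new
        active = active[shift > tol]
    return modes


def _merge_modes(modes: np.ndarray, radius: float) -> np.ndarray:
    """Greedy mode merging: modes closer than ``radius`` collapse; returns labels.

    Candidate modes are visited by decreasing support (number of converged
    seeds within ``radius``), ties by index, so the merge is deterministic.
    """
    tree = cKDTree(modes)
    support = np.array([len(nb) for nb in tree.query_ball_point(modes, r=radius)])
    order = np.lexsort((np.arange(len(modes)), -support))
    labels = np.full(len(modes), -1, dtype=np.int64)
    centers: list[np.ndarray] = []
    for i in order:
        if labels[i] >= 0:
            continue
        cid = len(centers)
        centers.append(modes[i])
        members = tree.query_ball_point(modes[i], r=radius)
        for m in members:
            if labels[m] < 0:
                labels[m] = cid
    return labels


def cluster_instances(ins_embed: np.ndarray, bandwidth: float = 0.6,
                      min_cluster_size: int | None = None,
                      tol: float = 1e-4, max_iter: int = 300) -> np.ndarray:
    """Instance ids from mean-shift on the embedding; see the module docstring."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(ins_embed, dtype=np.float64)
    n = len(x)
    if min_cluster_size is None:
        min_cluster_size = default_min_cluster_size(n)
    min_cluster_size = min(min_cluster_size, n)  # tiny clouds keep one cluster
    modes = mean_shift_modes(x, bandwidth, tol=tol, max_iter=max_iter)
    labels = _merge_modes(modes, radius=bandwidth / 2.0)

    # suppress speckle clusters: reassign members to the nearest surviving mode
    ids, counts = np.unique(labels, return_counts=True)
    surviving = ids[counts >= min_cluster_size]
    if len(surviving) == 0:
        surviving = ids[np.argsort(-counts)][:1]
    if len(surviving) < len(ids):
        centers = np.array([modes[labels == i].mean(axis=0) for i in surviving])
        doomed = ~np.isin(labels, surviving)
        nearest = np.argmin(
            np.linalg.norm(modes[doomed][:, None, :] - centers[None, :, :], axis=-1),
            axis=1)
        labels[doomed] = surviving[nearest]

    # contiguous ids by decreasing size; ties by old id for determinism
    ids, counts = np.unique(labels, return_counts=True)
    order = np.lexsort((ids, -counts))
    remap = {int(old): rank for rank, old in enumerate(ids[order])}
    return np.array([remap[int(l)] for l in labels], dtype=np.int64)


def assign_instance_class(sem_pred: np.ndarray, ins_pred: np.ndarray) -> dict[int, int]:
    """Majority semantic class per instance; ties resolve to the lowest class id."""
    sem_pred, ins_pred = np.asarray(sem_pred), np.asarray(ins_pred)
    if sem_pred.shape != ins_pred.shape:
        raise ValueError("labelings must cover the same points")
    out: dict[int, int] = {}
    for ins in np.unique(ins_pred):
        classes = sem_pred[ins_pred == ins]
        out[int(ins)] = int(np.argmax(np.bincount(classes - classes.min())) + classes.min())
    return out


def segment_cloud(network, coords: np.ndarray, bandwidth: float = 0.6,
                  min_cluster_size: int | None = None, seed: int = 0) -> SegmentationResult:
    """Forward pass + argmax + mean-shift, packaged as one call."""
    out = network.forward(coords, seed=seed)
    sem = predict_semantics(out.sem_logits.data)
    ins = cluster_instances(out.ins_embed.data, bandwidth=bandwidth,
                            min_cluster_size=min_cluster_size)
    return SegmentationResult(sem_pred=sem, ins_pred=ins,
                              ins_class=assign_instance_class(sem, ins))
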