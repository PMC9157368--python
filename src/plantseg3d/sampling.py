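"""Point-cloud downsampling: FPS, voxel-grid (VBS) and the hybrid VFPS.

Farthest-point sampling (FPS) greedily keeps the point with the largest
minimum distance to the already-kept set; it preserves extremes but, when the
input is far larger than the target size, concentrates picks on silhouette
edges and can leave interior cavities.  Voxel-based sampling (VBS) replaces
each occupied voxel by the centroid of its members, which evens out density
but gives a data-dependent output size.  VFPS chains the two: voxelize to
slightly more centroids than the target ``N``, then run FPS down to exactly
``N`` starting from a randomly chosen centroid.  The random start makes
repeated draws distinct, which is what the training pipeline uses as data
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import LabeledPointCloud

__all__ = [
    "VoxelGrid",
    "farthest_point_sample",
    "voxel_grid_sample",
    "auto_voxel_grid",
    "vfps",
    "augment_by_vfps",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: ``index = floor((coord - origin) / edge)``."""

    edge_lengths: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edge_lengths, dtype=np.float64)
        if edges.shape != (3,) or not np.all(edges > 0):
            raise ValueError("voxel edge lengths must be three positive reals")

    def voxel_indices(self, coords: np.ndarray) -> np.ndarray:
        edges = np.asarray(self.edge_lengths, dtype=np.float64)
        origin = np.asarray(self.origin, dtype=np.float64)
        return np.floor((coords - origin) / edges).astype(np.int64)


def farthest_point_sample(
    cloud: LabeledPointCloud | np.ndarray, n_samples: int, start: int = 0
) -> np.ndarray:
    """Greedy FPS; returns ``n_samples`` point indices, the first being ``start``.

    Each subsequent index maximizes the minimum Euclidean distance to the
    already-selected set; ties break toward the lowest index, so the result is
    deterministic given (cloud, n_samples, start).
    """
    coords = cloud.coords if isinstance(cloud, LabeledPointCloud) else coords_arg(cloud)
    n = len(coords)
    if n == 0:
        raise ValueError("cannot sample from an empty cloud")
    if not 1 <= n_samples <= n:
        raise ValueError(
            f"cannot sample more points than available ({n_samples} > {n})"
            if n_samples > n else "n_samples must be >= 1"
        )
    if not 0 <= start < n:
        raise ValueError("start index out of range")
    selected = np.empty(n_samples, dtype=np.int64)
    selected[0] = start
    # min distance from every point to the selected set, updated incrementally
    min_d2 = np.sum((coords - coords[start]) ** 2, axis=1)
    for i in range(1, n_samples):
        nxt = int(np.argmax(min_d2))  # argmax returns the first (lowest-index) max
        selected[i] = nxt
        d2 = np.sum((coords - coords[nxt]) ** 2, axis=1)
        np.minimum(min_d2, d2, out=min_d2)
    return selected


def coords_arg(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    return arr


def _majority(values: np.ndarray) -> int:
    """Majority vote; ties resolve to the lowest label id."""
    shifted = values - values.min()
    counts = np.bincount(shifted)
    return int(np.argmax(counts) + values.min())


def voxel_grid_sample(cloud: LabeledPointCloud, grid: VoxelGrid) -> LabeledPointCloud:
    """One centroid ("center of gravity") per occupied voxel.

    Labels, when present, are carried by per-voxel majority vote (ties to the
    lowest id).  The output size is data-dependent.
    """
    vox = grid.voxel_indices(cloud.coords)
    _, first, inverse = np.unique(vox, axis=0, return_index=True, return_inverse=True)
    n_vox = first.size
    counts = np.bincount(inverse, minlength=n_vox).astype(np.float64)
    centroids = np.empty((n_vox, 3))
    for axis in range(3):
        centroids[:, axis] = np.bincount(inverse, weights=cloud.coords[:, axis],
                                         minlength=n_vox) / counts
    # stable, grid-independent ordering: by first member point in input order
    order = np.argsort(first, kind="stable")
    centroids = centroids[order]
    rank = np.empty(n_vox, dtype=np.int64)
    rank[order] = np.arange(n_vox)
    inverse = rank[inverse]

    order_by_voxel = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order_by_voxel], np.arange(n_vox + 1))

    def vote(labels: np.ndarray) -> np.ndarray:
        out = np.empty(n_vox, dtype=np.int64)
        for v in range(n_vox):
            out[v] = _majority(labels[order_by_voxel[bounds[v]:bounds[v + 1]]])
        return out

    sem = ins = None
    if cloud.ins_label is not None:
        ins = vote(cloud.ins_label)
        if cloud.sem_label is not None:
            # instance ids are class-pure in the input, so the centroid's
            # semantic label follows its voted instance — votes stay consistent
            ins2sem = {int(i): int(cloud.sem_label[cloud.ins_label == i][0])
                       for i in np.unique(cloud.ins_label)}
            sem = np.array([ins2sem[int(i)] for i in ins], dtype=np.int64)
    elif cloud.sem_label is not None:
        sem = vote(cloud.sem_label)

    return LabeledPointCloud(
        coords=centroids,
        sem_label=sem,
        ins_label=ins,
        meta={**cloud.meta, "vbs_edges": tuple(grid.edge_lengths)},
    )


def _count_voxels(coords: np.ndarray, edge: float, origin: np.ndarray) -> int:
    vox = np.floor((coords - origin) / edge).astype(np.int64)
    return np.unique(vox, axis=0).shape[0]


def auto_voxel_grid(
    cloud: LabeledPointCloud, n_target: int, slack: float = 1.3, max_iter: int = 60
) -> VoxelGrid:
    """Bisect an isotropic edge length so VBS yields slightly more than ``n_target`` voxels.

    Searches ``[bbox_diag/1000, bbox_diag]`` for an occupied-voxel count in
    ``[n_target, slack * n_target]``; accepts the first grid in range, else the
    smallest count >= n_target seen.  The origin is the bounding-box minimum
    corner, so the grid is translation-invariant within the cloud.
    """
    coords = cloud.coords
    origin = coords.min(axis=0)
    diag = float(np.linalg.norm(coords.max(axis=0) - origin))
    if diag == 0.0:
        raise ValueError("degenerate cloud: all points coincide, achieved voxel count 1")
    lo, hi = diag / 1000.0, diag  # count(lo) is max, count(hi) is small
    best_edge, best_count = None, None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        count = _count_voxels(coords, mid, origin)
        if n_target <= count <= slack * n_target:
            return VoxelGrid((mid, mid, mid), tuple(origin))
        if count >= n_target and (best_count is None or count < best_count):
            best_edge, best_count = mid, count
        if count < n_target:
            hi = mid  # too coarse -> shrink edge
        else:
            lo = mid
    if best_edge is None:
        achieved = _count_voxels(coords, diag / 1000.0, origin)
        raise ValueError(
            f"auto voxel tuning failed: at the finest grid only {achieved} voxels "
            f"are occupied but {n_target} points were requested"
        )
    return VoxelGrid((best_edge, best_edge, best_edge), tuple(origin))


def vfps(
    cloud: LabeledPointCloud,
    n_samples: int,
    seed: int,
    grid: VoxelGrid | None = None,
) -> LabeledPointCloud:
    """Voxelized farthest-point sampling to exactly ``n_samples`` points.

    VBS first (auto-tuned isotropic grid unless one is given), then FPS on the
    centroids starting from a centroid drawn uniformly under ``seed``.  Every
    output point is bit-for-bit a VBS centroid.
    """
    if len(cloud) < n_samples:
        raise ValueError(
            f"cannot sample more points than available ({n_samples} > {len(cloud)})"
        )
    if grid is None:
        grid = auto_voxel_grid(cloud, n_samples)
    centroids = voxel_grid_sample(cloud, grid)
    if len(centroids) < n_samples:
        raise ValueError(
            f"voxel stage produced only {len(centroids)} centroids "
            f"but {n_samples} points were requested"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(centroids)))
    idx = farthest_point_sample(centroids, n_samples, start=start)
    return centroids.subset(idx, vfps_seed=seed, vfps_start=start)


def augment_by_vfps(
    cloud: LabeledPointCloud, n_samples: int, reps: int, base_seed: int = 0,
    grid: VoxelGrid | None = None,
) -> list[LabeledPointCloud]:
    """``reps`` VFPS draws with seeds ``base_seed .. base_seed + reps - 1``.

    The voxel stage is shared (it is seed-independent); only the FPS start
    varies, which is the sole source of randomness in the augmentation.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if grid is None:
        grid = auto_voxel_grid(cloud, n_samples)
    return [vfps(cloud, n_samples, seed=base_seed + r, grid=grid) for r in range(reps)]
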