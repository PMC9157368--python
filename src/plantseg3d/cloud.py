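"""Labeled point-cloud container and plain-text / PLY / HDF5 I/O.

A cloud is an ``n x 3`` array of coordinates (millimeters throughout the
package) with optional per-point integer semantic and instance labels.
Semantic ids live in ``[0, C)``; instance ids are non-negative, with ``-1``
meaning "unassigned".  A hard invariant is that one instance never spans two
semantic classes — each leaf belongs to exactly one organ class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "LabeledPointCloud",
    "read_ply",
    "write_ply",
    "read_xyz",
    "write_xyz",
    "save_batches_h5",
    "load_batches_h5",
]


@dataclass
class LabeledPointCloud:
    coords: np.ndarray
    sem_label: np.ndarray | None = None
    ins_label: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.coords) < 1:
            raise ValueError("a point cloud needs at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        for name in ("sem_label", "ins_label"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab, dtype=np.int64)
                if lab.shape != (len(self.coords),):
                    raise ValueError(f"{name} length must match point count")
                setattr(self, name, lab)
        self._check_instance_purity()

    def _check_instance_purity(self) -> None:
        if self.sem_label is None or self.ins_label is None:
            return
        mask = self.ins_label >= 0
        for ins in np.unique(self.ins_label[mask]):
            sems = np.unique(self.sem_label[self.ins_label == ins])
            if len(sems) > 1:
                raise ValueError(
                    f"instance {ins} spans semantic classes {sems.tolist()}"
                )

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def subset(self, idx: np.ndarray, **meta) -> "LabeledPointCloud":
        """Cloud restricted to the points at ``idx`` (labels carried along)."""
        idx = np.asarray(idx)
        return LabeledPointCloud(
            coords=self.coords[idx],
            sem_label=None if self.sem_label is None else self.sem_label[idx],
            ins_label=None if self.ins_label is None else self.ins_label[idx],
            meta={**self.meta, **meta},
        )


# ---------------------------------------------------------------------------
# ASCII PLY dialect: vertex props x y z [+ int sem_label, int ins_label]
# ---------------------------------------------------------------------------

def write_ply(cloud: LabeledPointCloud, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    cols: list[np.ndarray] = [cloud.coords]
    props = ["property float x", "property float y", "property float z"]
    fmt = ["%.8g", "%.8g", "%.8g"]
    if cloud.sem_label is not None:
        cols.append(cloud.sem_label[:, None].astype(np.float64))
        props.append("property int sem_label")
        fmt.append("%d")
    if cloud.ins_label is not None:
        cols.append(cloud.ins_label[:, None].astype(np.float64))
        props.append("property int ins_label")
        fmt.append("%d")
    body = np.hstack(cols)
    header = ["ply", "format ascii 1.0"]
    if comment:
        header += [f"comment {line}" for line in str(comment).splitlines()]
    header += [f"element vertex {len(cloud)}", *props, "end_header"]
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, body, fmt=" ".join(fmt))


def read_ply(path: str | Path) -> LabeledPointCloud:
    path = Path(path)
    with path.open() as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        n_vertex = None
        names: list[str] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unterminated PLY header")
            line = line.strip()
            if line.startswith("format") and "ascii" not in line:
                raise ValueError("only ASCII PLY is supported")
            if line.startswith("element"):
                _, name, count = line.split()
                in_vertex = name == "vertex"
                if in_vertex:
                    n_vertex = int(count)
            elif line.startswith("property") and in_vertex:
                names.append(line.split()[-1])
            elif line == "end_header":
                break
        if n_vertex is None:
            raise ValueError("PLY file has no vertex element")
        data = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    col = {name: data[:, i] for i, name in enumerate(names)}
    for axis in "xyz":
        if axis not in col:
            raise ValueError(f"PLY vertex element lacks property {axis}")
    coords = np.column_stack([col["x"], col["y"], col["z"]])
    sem = col.get("sem_label")
    ins = col.get("ins_label")
    return LabeledPointCloud(
        coords=coords,
        sem_label=None if sem is None else sem.astype(np.int64),
        ins_label=None if ins is None else ins.astype(np.int64),
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Whitespace text: "x y z [sem ins]" per line
# ---------------------------------------------------------------------------

def write_xyz(cloud: LabeledPointCloud, path: str | Path) -> None:
    cols = [cloud.coords]
    fmt = ["%.8g"] * 3
    if cloud.sem_label is not None and cloud.ins_label is not None:
        cols += [cloud.sem_label[:, None], cloud.ins_label[:, None]]
        fmt += ["%d", "%d"]
    np.savetxt(Path(path), np.hstack([np.asarray(c, dtype=np.float64) for c in cols]),
               fmt=" ".join(fmt))


def read_xyz(path: str | Path) -> LabeledPointCloud:
    data = np.loadtxt(Path(path), ndmin=2)
    if data.shape[1] not in (3, 5):
        raise ValueError("expected 3 (xyz) or 5 (xyz sem ins) columns")
    sem = ins = None
    if data.shape[1] == 5:
        sem = data[:, 3].astype(np.int64)
        ins = data[:, 4].astype(np.int64)
    return LabeledPointCloud(data[:, :3], sem, ins, meta={"source": str(path)})


# ---------------------------------------------------------------------------
# Fixed-size batches in HDF5 (training containers)
# ---------------------------------------------------------------------------

def save_batches_h5(clouds: Iterable[LabeledPointCloud], path: str | Path) -> None:
    """Store equally-sized labeled clouds as (B,N,3)/(B,N) HDF5 datasets."""
    import h5py

    clouds = list(clouds)
    sizes = {len(c) for c in clouds}
    if len(sizes) != 1:
        raise ValueError(f"all clouds in a batch file must share a size, got {sorted(sizes)}")
    coords = np.stack([c.coords for c in clouds])
    with h5py.File(Path(path), "w") as fh:
        fh.create_dataset("coords", data=coords)
        if all(c.sem_label is not None for c in clouds):
            fh.create_dataset("sem_label", data=np.stack([c.sem_label for c in clouds]))
        if all(c.ins_label is not None for c in clouds):
            fh.create_dataset("ins_label", data=np.stack([c.ins_label for c in clouds]))
        fh.attrs["meta"] = repr([c.meta for c in clouds])


def load_batches_h5(path: str | Path) -> list[LabeledPointCloud]:
    import ast

    import h5py

    with h5py.File(Path(path), "r") as fh:
        coords = np.asarray(fh["coords"])
        sem = np.asarray(fh["sem_label"]) if "sem_label" in fh else None
        ins = np.asarray(fh["ins_label"]) if "ins_label" in fh else None
        metas = ast.literal_eval(fh.attrs.get("meta", "[]"))
    out = []
    for b in range(len(coords)):
        out.append(LabeledPointCloud(
            coords[b],
            None if sem is None else sem[b],
            None if ins is None else ins[b],
            meta=metas[b] if b < len(metas) else {},
        ))
    return out
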