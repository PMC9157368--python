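"""Procedural generator of labeled multi-species plant point clouds.

The generator emulates laser-scanned crop clouds with the statistical
structure the segmentation pipeline assumes: a thin stem axis, 3-15 leaf
instances attached at distinct stem nodes, species-specific leaf morphology,
non-uniform point density (sparser toward the canopy top) and small additive
scan noise.  Three morphologies are produced:

* ``broadleaf``   - big elliptic leaf blades (tobacco-like),
* ``compoundleaf``- one large + two small leaflets per leaf sharing a single
                    instance id (tomato-like),
* ``slenderleaf`` - long, thin, twisted strap leaves (sorghum-like).

Semantic ids are fixed at C = 6: ``{0,1}`` stem/leaf of species A (broadleaf),
``{2,3}`` species B (compoundleaf), ``{4,5}`` species C (slenderleaf).  Each
leaf carries its own instance id; all stem points share one reserved stem
instance id (the largest id in the cloud) which downstream leaf-instance
evaluation ignores.

Units are millimeters; default plants are ~100-500 mm tall, and stems are a
clear minority of points, as in real crop scans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cloud import LabeledPointCloud
from .sampling import augment_by_vfps

__all__ = ["PlantSpec", "SPECIES", "SEMANTIC_NAMES", "STEM_CLASSES", "LEAF_CLASSES",
           "generate_plant", "generate_dataset"]

SPECIES = ("broadleaf", "compoundleaf", "slenderleaf")

#: semantic-class layout, fixed across the package (C = 6)
SEMANTIC_NAMES = {
    0: "broadleaf-stem", 1: "broadleaf-leaf",
    2: "compoundleaf-stem", 3: "compoundleaf-leaf",
    4: "slenderleaf-stem", 5: "slenderleaf-leaf",
}
STEM_CLASSES = (0, 2, 4)
LEAF_CLASSES = (1, 3, 5)

_NODE_SPACING_MM = 10.0  # minimum distance between leaf attachment nodes


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one synthetic plant.

    ``points_per_organ`` is an inclusive (low, high) range drawn per organ;
    ``density_gradient`` in [0, 1] thins points linearly with height (0 = none,
    1 = the canopy top is maximally sparse), reproducing the dense-bottom /
    sparse-top imbalance of real scans.  ``noise_sd`` is the isotropic Gaussian
    scan-noise standard deviation in mm.
    """

    species: str = "broadleaf"
    n_leaves: int = 6
    stem_height: float = 300.0
    leaf_size: float = 80.0
    points_per_organ: tuple[int, int] = (900, 1800)
    noise_sd: float = 0.05
    density_gradient: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}, expected one of {SPECIES}")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.stem_height <= 0 or self.leaf_size <= 0:
            raise ValueError("stem_height and leaf_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.density_gradient <= 1.0:
            raise ValueError("density_gradient must be in [0, 1]")

    @property
    def stem_class(self) -> int:
        return STEM_CLASSES[SPECIES.index(self.species)]

    @property
    def leaf_class(self) -> int:
        return LEAF_CLASSES[SPECIES.index(self.species)]


def _stem_curve(spec: PlantSpec, rng: np.random.Generator):
    """Smooth, mostly vertical space curve t in [0,1] -> xyz (mm)."""
    lean = rng.normal(0.0, 0.03 * spec.stem_height, size=2)
    bow = rng.normal(0.0, 0.05 * spec.stem_height, size=2)
    phase = rng.uniform(0, 2 * np.pi)

    def curve(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        x = lean[0] * t + bow[0] * np.sin(np.pi * t + phase) * t
        y = lean[1] * t + bow[1] * np.sin(np.pi * t) * t
        z = spec.stem_height * t
        return np.stack([x, y, z], axis=-1)

    return curve


def _tube_points(curve, n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    t = rng.uniform(0.0, 1.0, n)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    base = curve(t)
    # local frame approximated by global XY: stems are near-vertical
    offset = np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n)], axis=-1)
    return base + offset


def _rotation(azimuth: float, pitch: float) -> np.ndarray:
    ca, sa = np.cos(azimuth), np.sin(azimuth)
    cp, sp = np.cos(pitch), np.sin(pitch)
    rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    ry = np.array([[cp, 0, sp], [0, 1.0, 0], [-sp, 0, cp]])
    return rz @ ry


def _ellipse_patch(n: int, a: float, b: float, bend: float, rng: np.random.Generator) -> np.ndarray:
    """Points on a mildly curved elliptic blade in its local frame (x = outward)."""
    u = rng.uniform(-1.0, 1.0, n)
    v = rng.uniform(-1.0, 1.0, n)
    keep = u**2 + v**2 <= 1.0
    u, v = u[keep], v[keep]
    x = a * (u + 1.0)  # blade extends outward from the attachment point
    y = b * v
    z = bend * a * (u**2 + v**2)  # quadratic cupping keeps the blade thin but not planar
    return np.stack([x, y, z], axis=-1)


def _strap_leaf(n: int, length: float, width: float, rng: np.random.Generator) -> np.ndarray:
    """Long thin twisted strip: arcs up then droops, twisting about its axis."""
    t = rng.uniform(0.0, 1.0, n)
    w = rng.uniform(-0.5, 0.5, n) * width
    twist = rng.uniform(1.0, 2.0)
    droop = rng.uniform(0.6, 1.2)
    x = length * t
    y = w * np.cos(twist * t)
    z = length * (0.45 * np.sin(np.pi * t * 0.9) - droop * t**2 * 0.35) + w * np.sin(twist * t)
    return np.stack([x, y, z], axis=-1)


def _leaf_points(spec: PlantSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    s = spec.leaf_size
    if spec.species == "broadleaf":
        # tobacco-like: one very large, strongly cupped blade filling most of
        # the leaf footprint — the single-blade area is the species signature
        return _ellipse_patch(n, 0.8 * s, 0.5 * s, rng.uniform(0.3, 0.5), rng)
    if spec.species == "slenderleaf":
        # sorghum-like strap: long arc, ~30% of leaf_size wide, gentle twist
        return _strap_leaf(n, rng.uniform(2.0, 3.0) * s, 0.3 * s, rng)
    # compoundleaf: tomato-like pinnate leaf — one terminal leaflet and two
    # separated small lateral leaflets sharing the leaf's instance id;
    # leaflet centroids stay within one leaf_size of each other.
    n_big = n // 2
    n_small = (n - n_big) // 2
    big = _ellipse_patch(n_big, 0.24 * s, 0.15 * s, 0.25, rng) + np.array([0.62 * s, 0.0, 0.0])
    left = _ellipse_patch(n_small, 0.16 * s, 0.11 * s, 0.25, rng)
    right = _ellipse_patch(n - n_big - n_small, 0.16 * s, 0.11 * s, 0.25, rng)
    left = left @ _rotation(np.pi / 2.2, 0.0).T + np.array([0.26 * s, 0.12 * s, 0.0])
    right = right @ _rotation(-np.pi / 2.2, 0.0).T + np.array([0.26 * s, -0.12 * s, 0.0])
    return np.vstack([big, left, right])


def _thin_by_height(coords: np.ndarray, gradient: float, z_max: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Keep-mask implementing the dense-bottom / sparse-top density profile."""
    if gradient <= 0 or z_max <= 0:
        return np.ones(len(coords), dtype=bool)
    rel = np.clip(coords[:, 2] / z_max, 0.0, 1.0)
    keep_p = 1.0 - gradient * rel
    keep = rng.uniform(size=len(coords)) < keep_p
    if not keep.any():
        keep[int(rng.integers(len(coords)))] = True
    return keep


def generate_plant(spec: PlantSpec) -> LabeledPointCloud:
    """One labeled plant; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    max_nodes = int((0.8 * spec.stem_height) // _NODE_SPACING_MM)
    if spec.n_leaves > max_nodes:
        raise ValueError(
            f"impossible geometry: {spec.n_leaves} leaves but only "
            f"{max_nodes} stem nodes available on a {spec.stem_height} mm stem"
        )
    curve = _stem_curve(spec, rng)
    lo, hi = spec.points_per_organ
    n_stem = int(rng.integers(lo, hi + 1))
    stem_radius = max(1.5, 0.01 * spec.stem_height)
    stem = _tube_points(curve, n_stem, stem_radius, rng)

    # distinct attachment heights, phyllotactic-ish azimuth sequence
    node_t = np.sort(rng.choice(np.linspace(0.2, 1.0, max_nodes), spec.n_leaves,
                                replace=False))
    golden = np.deg2rad(137.5)
    parts = [stem]
    sems = [np.full(n_stem, spec.stem_class, dtype=np.int64)]
    inss = [np.full(n_stem, spec.n_leaves, dtype=np.int64)]  # reserved stem instance
    for leaf_id in range(spec.n_leaves):
        n_leaf = int(rng.integers(lo, hi + 1))
        local = _leaf_points(spec, n_leaf, rng)
        azimuth = golden * leaf_id + rng.normal(0.0, 0.2)
        pitch = rng.uniform(0.15 * np.pi, 0.35 * np.pi)
        pts = local @ _rotation(azimuth, pitch).T + curve(node_t[leaf_id])
        parts.append(pts)
        sems.append(np.full(len(pts), spec.leaf_class, dtype=np.int64))
        inss.append(np.full(len(pts), leaf_id, dtype=np.int64))

    coords = np.vstack(parts)
    sem = np.concatenate(sems)
    ins = np.concatenate(inss)

    keep = _thin_by_height(coords, spec.density_gradient, coords[:, 2].max(), rng)
    # never drop an organ entirely
    for organ in np.unique(ins):
        organ_idx = np.flatnonzero(ins == organ)
        if not keep[organ_idx].any():
            keep[organ_idx[0]] = True
    coords, sem, ins = coords[keep], sem[keep], ins[keep]

    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)

    return LabeledPointCloud(
        coords=coords, sem_label=sem, ins_label=ins,
        meta={"species": spec.species, "seed": spec.seed,
              "n_leaves": spec.n_leaves, "stem_instance": spec.n_leaves},
    )


def generate_dataset(
    n_plants_per_species: int,
    n_points: int = 4096,
    reps: int = 10,
    seed: int = 0,
    split_ratio: tuple[int, int] = (2, 1),
    base_spec: PlantSpec | None = None,
    n_leaves_ranges: dict[str, tuple[int, int]] | None = None,
) -> tuple[list[LabeledPointCloud], list[LabeledPointCloud], dict]:
    """Generate, split 'train : test' at the plant level, then VFPS-augment.

    Splitting happens *before* augmentation so the ``reps`` draws of one plant
    never straddle the train/test boundary.  Returns
    ``(train_clouds, test_clouds, manifest)``; the manifest records every seed.

    ``n_leaves_ranges`` overrides the species-typical leaf-count ranges; small
    target sizes use fewer leaves so each instance keeps a point count
    proportionate to the full-scale conditions.
    """
    if n_plants_per_species < 1:
        raise ValueError("need at least one plant per species")
    if sum(split_ratio) <= 0 or min(split_ratio) < 0:
        raise ValueError("invalid split ratio")
    master = np.random.default_rng(seed)
    n_train = int(round(n_plants_per_species * split_ratio[0] / sum(split_ratio)))
    n_train = min(max(n_train, 0 if split_ratio[0] == 0 else 1), n_plants_per_species)

    train: list[LabeledPointCloud] = []
    test: list[LabeledPointCloud] = []
    manifest: dict = {"master_seed": int(seed), "n_points": int(n_points),
                      "reps": int(reps), "plants": []}
    base = base_spec or PlantSpec()
    # species-typical habit: plant proportions and leaf counts differ between
    # crops, which is what makes species recognizable across individuals
    # leaf features must stay resolvable after downsampling: at N ~ 512 the
    # voxel stage runs at a ~20 mm edge, so species-defining structure sits
    # at the >= 30 mm scale
    habit = {
        "broadleaf": {"stem_height": 240.0, "leaf_size": 130.0, "n_leaves": (4, 7)},
        "compoundleaf": {"stem_height": 320.0, "leaf_size": 140.0, "n_leaves": (5, 9)},
        "slenderleaf": {"stem_height": 420.0, "leaf_size": 80.0, "n_leaves": (5, 9)},
    }
    for species in SPECIES:
        hb = habit[species]
        leaf_range = (n_leaves_ranges or {}).get(species, hb["n_leaves"])
        for p in range(n_plants_per_species):
            plant_seed = int(master.integers(2**31 - 1))
            vfps_seed = int(master.integers(2**30))
            n_leaves = int(master.integers(*leaf_range))
            spec = replace(base, species=species, n_leaves=n_leaves,
                           stem_height=hb["stem_height"], leaf_size=hb["leaf_size"],
                           seed=plant_seed)
            plant = generate_plant(spec)
            draws = augment_by_vfps(plant, n_points, reps=reps, base_seed=vfps_seed)
            split = "train" if p < n_train else "test"
            (train if split == "train" else test).extend(draws)
            manifest["plants"].append({
                "species": species, "plant_index": p, "split": split,
                "plant_seed": plant_seed, "n_leaves": n_leaves,
                "vfps_seeds": list(range(vfps_seed, vfps_seed + reps)),
            })
    return train, test, manifest
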