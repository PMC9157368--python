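"""Dual-task point-cloud segmentation network.

Architecture, front to back:

1. **Encoder** - four dual-neighborhood feature-extraction blocks,
   each preceded by farthest-point subsampling of the point set
   (N -> level_points[0] -> ... -> level_points[3]).  A block runs three
   similar stages; each stage combines a *position encoding* of the k-NN
   neighborhood in the original XYZ space (a 10-d vector per neighbor:
   ``p_i ∪ p_ik ∪ (p_i - p_ik) ∪ ||p_i - p_ik||``) with an *EdgeConv* over the
   k-NN neighborhood of the current feature space
   (``h_ik = MLP(f_i ∪ (f_i - f_ik))``), fused by *attentive pooling*
   (``f'_i = MLP(Σ_k w_ik (h_ik ∪ r_ik))`` with softmaxed learned scores).
   Skip rules: stage-1 output is concatenated onto stage-2's output to feed
   stage 3, and stage-2's output is added residually to stage-3's; stage 1
   has no skip.
2. **Double-granularity fusion** - two parallel decoders (a shallow,
   coarse-grained one and a deep, fine-grained one) interpolate features back
   to full resolution with inverse-distance-weighted 3-NN interpolation plus
   level skips; their outputs are averaged/concatenated and passed through a
   pointwise convolution + ReLU into the fused feature map (N x fused).
3. **Twin attention branches** (parameters not shared): spatial attention
   (per-point scalar gate from channel-average + sigmoid) then channel
   attention (per-channel gate from point-wise mean/max pooling, two
   pointwise convolutions, sum, sigmoid), followed by a pointwise head:
   an ``N x 5`` instance embedding and ``N x C`` semantic logits.

XYZ k-NN graphs, FPS indices and interpolation weights are discrete and
treated as constants of the autodiff graph; feature-space k-NN is recomputed
per stage from the current features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .autodiff import Parameter, Tensor, concatenate
from .sampling import farthest_point_sample

__all__ = [
    "NetworkConfig", "EmbeddingOutput", "SegmentationNetwork",
    "position_encode", "position_encode_graph", "edge_conv_inputs",
    "attentive_pool", "spatial_attention", "channel_attention",
    "knn_indices", "ABLATION_VERSIONS", "apply_ablation",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters (defaults follow the full-scale model)."""

    n_points: int = 4096
    n_classes: int = 6
    k_schedule: tuple[int, ...] = (16, 16, 8, 8)
    level_points: tuple[int, ...] = (1024, 512, 256, 128)
    level_channels: tuple[int, ...] = (64, 128, 256, 512)
    fused_channels: int = 128
    embed_dim: int = 5
    # input normalization: per-cloud centering plus unit-sphere scaling by
    # default (``None``); a positive value divides by that fixed constant
    # (mm) instead, keeping absolute organ sizes visible
    coord_scale: float | None = None
    # ablation switches: disabled modules are replaced by depth-preserving
    # pointwise MLPs so the network keeps (almost exactly) its parameter count
    use_encoder_blocks: bool = True
    use_dual_decoder: bool = True
    use_sa: bool = True
    use_ca: bool = True
    encoder_stage1_only: bool = False

    def __post_init__(self) -> None:
        lp = self.level_points
        if any(b >= a for a, b in zip(lp, lp[1:])):
            raise ValueError("level_points must be strictly decreasing")
        if lp[0] > self.n_points:
            raise ValueError("first encoder level larger than the input cloud")
        if len(self.k_schedule) != len(lp) or len(self.level_channels) != len(lp):
            raise ValueError("k_schedule/level_channels must match level count")
        for k, n in zip(self.k_schedule, lp):
            if not 1 <= k <= n:
                raise ValueError(f"neighborhood size {k} invalid for a {n}-point level")

    @property
    def lift_channels(self) -> int:
        return max(8, self.level_channels[0] // 4)


@dataclass
class EmbeddingOutput:
    """Per-point network outputs (autodiff tensors; use ``.data`` for arrays)."""

    sem_logits: Tensor   # N x C
    ins_embed: Tensor    # N x embed_dim
    fused: Tensor        # N x fused_channels (retained for the pairwise hinge loss)


# ---------------------------------------------------------------------------
# Functional pieces (also exercised directly by the unit tests)
# ---------------------------------------------------------------------------

def position_encode(p_i: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """10-d relative position encoding of each neighbor of one point."""
    p_i = np.asarray(p_i, dtype=np.float64).reshape(3)
    nb = np.asarray(neighbors, dtype=np.float64).reshape(-1, 3)
    diff = p_i[None, :] - nb
    dist = np.linalg.norm(diff, axis=1, keepdims=True)
    return np.hstack([np.broadcast_to(p_i, nb.shape), nb, diff, dist])


def position_encode_graph(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorized position encoding for an (n, K) neighbor-index graph."""
    nb = coords[idx]                               # (n, K, 3)
    pi = np.broadcast_to(coords[:, None, :], nb.shape)
    diff = pi - nb
    dist = np.linalg.norm(diff, axis=-1, keepdims=True)
    return np.concatenate([pi, nb, diff, dist], axis=-1)


def edge_conv_inputs(f: Tensor, idx: np.ndarray) -> Tensor:
    """EdgeConv pre-MLP tensor ``f_i ∪ (f_i - f_ik)`` of shape (n, K, 2D)."""
    n, k = idx.shape
    self_idx = np.broadcast_to(np.arange(n)[:, None], (n, k))
    fi = f.take(self_idx)
    fk = f.take(idx)
    return concatenate([fi, fi - fk], axis=-1)


def attentive_pool(h: Tensor, r, score_w, mlp) -> Tensor:
    """Softmax-weighted pooling of the concatenated (h ∪ r) neighborhood.

    ``h`` is (n, K, D), ``r`` (n, K, 10); scores come from a learned linear
    map over the concatenation, softmaxed over the K neighbors, so the
    weights are non-negative and sum to one (a generalized average pooling).
    The scoring map carries no bias: the softmax is shift-invariant, so a
    bias would be a structurally dead parameter.  ``mlp`` maps the pooled
    (n, D+10) vector to the stage output.
    """
    cat = concatenate([h, Tensor(r) if not isinstance(r, Tensor) else r], axis=-1)
    n, k, d = cat.shape
    scores = (cat.reshape(n * k, d) @ score_w).reshape(n, k, 1)
    w = _softmax_axis(scores, axis=1)
    pooled = (w * cat).sum(axis=1)                     # (n, D+10)
    return mlp(pooled)


def spatial_attention(F: Tensor) -> Tensor:
    """Per-point scalar gate: sigmoid of the channel-wise average."""
    gate = F.mean(axis=1, keepdims=True).sigmoid()   # (n, 1)
    return F * gate


def channel_attention(F: Tensor, w_avg, b_avg, w_max, b_max) -> Tensor:
    """Per-channel gate from mean- and max-pooling over points.

    The two 1 x D summaries each pass a pointwise convolution, are summed and
    squashed by a sigmoid into channel weights multiplied onto every row.
    With identity convolutions the gate is exactly ``sigmoid(mean + max)``.
    """
    avg = F.mean(axis=0, keepdims=True)
    mx = F.max(axis=0, keepdims=True)
    gate = ((avg @ w_avg + b_avg) + (mx @ w_max + b_max)).sigmoid()
    return F * gate


def knn_indices(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic k-NN (self included), ties broken by index order."""
    # squared distances via the expansion trick; partial sort then order the k
    sq = np.einsum("ij,ij->i", points, points)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (points @ points.T)
    if k >= len(points):
        return np.argsort(d2, axis=1, kind="stable")
    part = np.argpartition(d2, k - 1, axis=1)[:, :k]
    rows = np.arange(len(points))[:, None]
    order = np.argsort(d2[rows, part], axis=1, kind="stable")
    return part[rows, order]


def interp_weights(src: np.ndarray, dst: np.ndarray, k: int = 3):
    """Inverse-distance weights of the k nearest source points per target."""
    k = min(k, len(src))
    tree = cKDTree(src)
    dist, idx = tree.query(dst, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    w = 1.0 / (dist + 1e-10)
    w = w / w.sum(axis=1, keepdims=True)
    return idx, w


# ---------------------------------------------------------------------------
# Forward plan: all discrete per-cloud structure, cacheable across steps
# ---------------------------------------------------------------------------

@dataclass
class ForwardPlan:
    coords: np.ndarray                       # normalized N x 3
    center: np.ndarray
    scale: float
    level_coords: list = field(default_factory=list)   # coords per level
    level_index: list = field(default_factory=list)    # FPS picks into previous level
    xyz_knn: list = field(default_factory=list)        # per block (n_l, K)
    pos_enc: list = field(default_factory=list)        # per block (n_l, K, 10)
    fine_hops: list = field(default_factory=list)      # (dst_level, idx, w)
    coarse_hops: list = field(default_factory=list)


ABLATION_VERSIONS = {
    "A1": {"use_sa": False, "use_ca": False},
    "A2": {"use_sa": False},
    "A3": {"use_ca": False},
    "A4": {"use_dual_decoder": False},
    "A5": {"use_encoder_blocks": False},
    "A6": {},                       # VFPS -> FPS: a sampling switch, no network change
    "A7": {"encoder_stage1_only": True},
}


def apply_ablation(config: NetworkConfig, version: str) -> NetworkConfig:
    """Return a copy of ``config`` with one ablation version's switches set."""
    from dataclasses import replace

    if version not in ABLATION_VERSIONS:
        raise ValueError(f"unknown ablation version {version!r}")
    return replace(config, **ABLATION_VERSIONS[version])


class SegmentationNetwork:
    """The full forward model; parameters live in ``self.params``."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, Parameter] = {}
        self._rng = np.random.default_rng(seed)
        self._build()

    def train_mode(self, training: bool = True) -> None:
        """Kept for interface symmetry; the forward pass has no mode-dependent
        layers, so training and inference behave identically."""

    # -- parameter plumbing -------------------------------------------------
    def _linear(self, name: str, din: int, dout: int, scale: float | None = None) -> None:
        std = scale if scale is not None else np.sqrt(2.0 / din)
        self.params[f"{name}.w"] = Parameter(self._rng.normal(0.0, std, size=(din, dout)))
        self.params[f"{name}.b"] = Parameter(np.zeros(dout))

    def _apply(self, name: str, x: Tensor, relu: bool = True) -> Tensor:
        """Shared pointwise convolution (linear + optional ReLU)."""
        w, b = self.params[f"{name}.w"], self.params[f"{name}.b"]
        if x.ndim == 3:  # flatten to one GEMM: 3-d matmul loops tiny BLAS calls
            n, k, d = x.shape
            return ((x.reshape(n * k, d) @ w + b).reshape(n, k, w.shape[1]).relu()
                    if relu else (x.reshape(n * k, d) @ w + b).reshape(n, k, w.shape[1]))
        out = x @ w + b
        return out.relu() if relu else out

    def parameters(self) -> dict[str, Parameter]:
        return self.params

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k}")
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    # -- construction -------------------------------------------------------
    def _stage_is_real(self, stage: int) -> bool:
        if not self.config.use_encoder_blocks:
            return False
        if self.config.encoder_stage1_only and stage > 0:
            return False
        return True

    def _build(self) -> None:
        cfg = self.config
        self._linear("lift", 3, cfg.lift_channels)
        d_in = cfg.lift_channels
        for b, width in enumerate(cfg.level_channels):
            stage_in = (d_in, width, 2 * width)
            for s in range(3):
                # layer shapes are identical whether the stage is a real
                # neighborhood stage or its depth-preserving pointwise stand-in,
                # so ablations keep the parameter count (minus tiny score layers)
                self._linear(f"block{b}.s{s}.edge", 2 * stage_in[s], width)
                if self._stage_is_real(s):
                    self.params[f"block{b}.s{s}.score.w"] = Parameter(
                        self._rng.normal(0.0, 0.1, size=(width + 10, 1)))
                self._linear(f"block{b}.s{s}.post", width + 10, width)
            d_in = width

        dec = cfg.fused_channels
        # fine decoder: one hop per encoder level, deepest to full resolution
        fine_skips = list(cfg.level_channels[-2::-1]) + [cfg.lift_channels]
        d = cfg.level_channels[-1]
        for h, skip in enumerate(fine_skips):
            self._linear(f"fine.hop{h}", d + skip, dec)
            d = dec
        if cfg.use_dual_decoder:
            # coarse decoder: every other level (half the hops)
            coarse_skips = [cfg.level_channels[-3], cfg.lift_channels]
            d = cfg.level_channels[-1]
            for h, skip in enumerate(coarse_skips):
                self._linear(f"coarse.hop{h}", d + skip, dec)
                d = dec
        self._linear("fuse", 3 * dec, cfg.fused_channels)

        for branch in ("ins", "sem"):
            if cfg.use_sa:
                pass  # spatial attention is parameter-free
            else:
                self._linear(f"{branch}.sa_mlp", cfg.fused_channels, cfg.fused_channels)
            if cfg.use_ca:
                self._linear(f"{branch}.ca_avg", cfg.fused_channels, cfg.fused_channels)
                self._linear(f"{branch}.ca_max", cfg.fused_channels, cfg.fused_channels)
            else:
                self._linear(f"{branch}.ca_mlp", cfg.fused_channels, cfg.fused_channels)
        self._linear("ins.head", cfg.fused_channels, cfg.embed_dim, scale=0.1)
        self._linear("sem.head", cfg.fused_channels, cfg.n_classes, scale=0.1)

    # -- plan ---------------------------------------------------------------
    def prepare(self, coords: np.ndarray, seed: int = 0) -> ForwardPlan:
        """Precompute the discrete structure of one cloud's forward pass."""
        cfg = self.config
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (cfg.n_points, 3):
            raise ValueError(
                f"expected a ({cfg.n_points}, 3) cloud, got {coords.shape}")
        center = coords.mean(axis=0)
        centered = coords - center
        if cfg.coord_scale is not None:
            scale = float(cfg.coord_scale)
        else:
            scale = float(np.max(np.linalg.norm(centered, axis=1))) or 1.0
        norm = centered / scale
        plan = ForwardPlan(coords=norm, center=center, scale=scale)

        rng = np.random.default_rng(seed)
        prev = norm
        for b, n_level in enumerate(cfg.level_points):
            # geometric seeded start: the extreme point along a random direction.
            # Unlike a random index this commutes with point reordering, keeping
            # the whole forward pass permutation-equivariant.
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            start = int(np.argmax(prev @ u))
            idx = farthest_point_sample(prev, n_level, start=start)
            level = prev[idx]
            plan.level_index.append(idx)
            plan.level_coords.append(level)
            k = cfg.k_schedule[b]
            knn = knn_indices(level, k)
            plan.xyz_knn.append(knn)
            plan.pos_enc.append(position_encode_graph(level, knn))
            prev = level

        levels = [norm] + plan.level_coords        # index 0 = full resolution
        fine_path = list(range(len(cfg.level_points) - 1, -1, -1))  # 3,2,1,0
        src = len(cfg.level_points)
        for dst in fine_path:
            idx, w = interp_weights(levels[src], levels[dst], k=3)
            plan.fine_hops.append((dst, idx, w))
            src = dst
        if cfg.use_dual_decoder:
            src = len(cfg.level_points)
            for dst in (len(cfg.level_points) - 2, 0):
                idx, w = interp_weights(levels[src], levels[dst], k=3)
                plan.coarse_hops.append((dst, idx, w))
                src = dst
        return plan

    # -- forward ------------------------------------------------------------
    def _stage(self, b: int, s: int, f: Tensor, plan: ForwardPlan) -> Tensor:
        if self._stage_is_real(s):
            k = self.config.k_schedule[b]
            idx_f = knn_indices(f.data, min(k, len(f.data)))
            edge_in = edge_conv_inputs(f, idx_f)               # (n, K, 2D)
            h = self._apply(f"block{b}.s{s}.edge", edge_in)    # (n, K, W)
            return attentive_pool(
                h, plan.pos_enc[b],
                self.params[f"block{b}.s{s}.score.w"],
                lambda pooled: self._apply(f"block{b}.s{s}.post", pooled))
        # depth-preserving pointwise stand-in: same layer shapes, no neighborhoods
        h = self._apply(f"block{b}.s{s}.edge", concatenate([f, f], axis=-1))
        n = len(h.data)
        pad = np.zeros((n, 10))
        pad[:, :3] = plan.level_coords[b]
        return self._apply(f"block{b}.s{s}.post",
                           concatenate([h, Tensor(pad)], axis=-1))

    def _block(self, b: int, f: Tensor, plan: ForwardPlan) -> Tensor:
        out1 = self._stage(b, 0, f, plan)
        out2 = self._stage(b, 1, out1, plan)
        out3 = self._stage(b, 2, concatenate([out1, out2], axis=-1), plan)
        return out2 + out3

    def _decode(self, hops: list, prefix: str, feats_per_level: list) -> Tensor:
        f = feats_per_level[-1]
        for h, (dst, idx, w) in enumerate(hops):
            gathered = f.take(idx)                             # (n_dst, 3, D)
            up = (Tensor(w[:, :, None]) * gathered).sum(axis=1)
            f = self._apply(f"{prefix}.hop{h}", concatenate(
                [up, feats_per_level[dst]], axis=-1))
        return f

    def _branch(self, name: str, F: Tensor) -> Tensor:
        cfg = self.config
        if cfg.use_sa:
            F = spatial_attention(F)
        else:
            F = self._apply(f"{name}.sa_mlp", F)
        if cfg.use_ca:
            F = channel_attention(F,
                                  self.params[f"{name}.ca_avg.w"],
                                  self.params[f"{name}.ca_avg.b"],
                                  self.params[f"{name}.ca_max.w"],
                                  self.params[f"{name}.ca_max.b"])
        else:
            F = self._apply(f"{name}.ca_mlp", F)
        return self._apply(f"{name}.head", F, relu=False)

    def forward(self, coords_or_plan, seed: int = 0) -> EmbeddingOutput:
        plan = (coords_or_plan if isinstance(coords_or_plan, ForwardPlan)
                else self.prepare(coords_or_plan, seed=seed))
        f0 = self._apply("lift", Tensor(plan.coords))
        feats = [f0]
        f = f0
        for b in range(len(self.config.level_points)):
            f = f.take(plan.level_index[b])
            f = self._block(b, f, plan)
            feats.append(f)
        F_f = self._decode(plan.fine_hops, "fine", feats)
        if self.config.use_dual_decoder:
            F_c = self._decode(plan.coarse_hops, "coarse", feats)
        else:
            F_c = F_f
        merged = concatenate([F_c, F_f, (F_c + F_f) * 0.5], axis=-1)
        fused = self._apply("fuse", merged)
        return EmbeddingOutput(
            sem_logits=self._branch("sem", fused),
            ins_embed=self._branch("ins", fused),
            fused=fused,
        )


def _softmax_axis(x: Tensor, axis: int) -> Tensor:
    from .autodiff import log_softmax

    return log_softmax(x, axis=axis).exp()
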