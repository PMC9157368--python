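"""scikit-learn-style estimators wrapping the segmentation pipeline.

``PlantSegmenter`` is the fit/predict surface: ``fit`` trains the dual-task
network on a list of labeled, fixed-size clouds; ``predict`` returns discrete
semantic + instance labelings; ``score`` is mean per-point semantic accuracy.
``MeanShiftInstances`` exposes the embedding-space clustering step alone as a
clusterer.  Both follow sklearn conventions (``get_params``/``set_params``,
fitted attributes with a trailing underscore) and compose with sklearn's
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .cloud import LabeledPointCloud
from .inference import (SegmentationResult, assign_instance_class,
                        cluster_instances, predict_semantics)
from .losses import LossParams
from .network import NetworkConfig, SegmentationNetwork
from .train import TrainConfig, train

__all__ = ["PlantSegmenter", "MeanShiftInstances"]


class PlantSegmenter(BaseEstimator):
    """Dual-task (organ semantics + leaf instances) point-cloud segmenter.

    Parameters mirror the network / training configuration; ``network_config``
    and ``loss_params`` accept full config objects, with ``None`` meaning the
    package defaults.
    """

    def __init__(self, network_config: NetworkConfig | None = None,
                 loss_params: LossParams | None = None,
                 batch_size: int = 8, learning_rate: float = 0.002,
                 lr_decay: float = 0.7, lr_decay_every: int = 10,
                 epochs: int = 190, max_steps: int | None = None,
                 bandwidth: float = 0.6, min_cluster_size: int | None = None,
                 seed: int = 0):
        self.network_config = network_config
        self.loss_params = loss_params
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.lr_decay_every = lr_decay_every
        self.epochs = epochs
        self.max_steps = max_steps
        self.bandwidth = bandwidth
        self.min_cluster_size = min_cluster_size
        self.seed = seed

    # -- sklearn API --------------------------------------------------------
    def fit(self, X: list[LabeledPointCloud], y=None,
            X_val: list[LabeledPointCloud] | None = None) -> "PlantSegmenter":
        """Train on labeled clouds; ``X_val`` drives minimum-test-loss selection."""
        cfg = self.network_config or NetworkConfig()
        self.network_ = SegmentationNetwork(cfg, seed=self.seed)
        tcfg = TrainConfig(batch_size=self.batch_size,
                           initial_lr=self.learning_rate,
                           lr_decay=self.lr_decay,
                           lr_decay_every=self.lr_decay_every,
                           epochs=self.epochs, max_steps=self.max_steps,
                           seed=self.seed)
        best, log = train(self.network_, X, X_val, tcfg,
                          self.loss_params or LossParams())
        self.network_.load_state_dict(best["state"])
        self.best_test_loss_ = best["loss"]
        self.loss_log_ = log
        self.n_steps_ = len(log)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("this PlantSegmenter instance is not fitted yet")

    def predict_one(self, cloud: LabeledPointCloud | np.ndarray) -> SegmentationResult:
        self._check_fitted()
        coords = cloud.coords if isinstance(cloud, LabeledPointCloud) else np.asarray(cloud)
        out = self.network_.forward(coords, seed=0)
        sem = predict_semantics(out.sem_logits.data)
        ins = cluster_instances(out.ins_embed.data, bandwidth=self.bandwidth,
                                min_cluster_size=self.min_cluster_size)
        return SegmentationResult(sem_pred=sem, ins_pred=ins,
                                  ins_class=assign_instance_class(sem, ins))

    def predict(self, X) -> list[SegmentationResult]:
        if isinstance(X, (LabeledPointCloud, np.ndarray)):
            return [self.predict_one(X)]
        return [self.predict_one(c) for c in X]

    def score(self, X: list[LabeledPointCloud], y=None) -> float:
        """Mean per-point semantic accuracy over labeled clouds."""
        self._check_fitted()
        accs = []
        for cloud in ([X] if isinstance(X, LabeledPointCloud) else X):
            if cloud.sem_label is None:
                raise ValueError("score requires semantic labels")
            res = self.predict_one(cloud)
            accs.append(float(np.mean(res.sem_pred == cloud.sem_label)))
        return float(np.mean(accs))


class MeanShiftInstances(BaseEstimator, ClusterMixin):
    """Flat-kernel mean-shift instance extraction as a standalone clusterer."""

    def __init__(self, bandwidth: float = 0.6, min_cluster_size: int | None = None,
                 tol: float = 1e-4, max_iter: int = 300):
        self.bandwidth = bandwidth
        self.min_cluster_size = min_cluster_size
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "MeanShiftInstances":
        self.labels_ = cluster_instances(
            np.asarray(X), bandwidth=self.bandwidth,
            min_cluster_size=self.min_cluster_size,
            tol=self.tol, max_iter=self.max_iter)
        self.n_clusters_ = int(self.labels_.max()) + 1
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
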