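"""End-to-end desk-scale experiment: generate, train, evaluate.

One function drives the whole pipeline under the toy profile so the same
computation backs the acceptance checks, the command-line workflow and the
worked example in the README.
"""

from __future__ import annotations

import numpy as np

from .inference import (assign_instance_class, cluster_instances,
                        predict_semantics)
from .losses import LossParams
from .metrics import evaluate_cloud, report
from .network import NetworkConfig, SegmentationNetwork
from .plantgen import LEAF_CLASSES, PlantSpec, generate_dataset
from .train import TrainConfig, train

__all__ = ["toy_network_config", "toy_train_config", "run_toy_experiment"]


def toy_network_config() -> NetworkConfig:
    return NetworkConfig(n_points=512, level_points=(128, 64, 32, 16),
                         level_channels=(16, 32, 64, 128), fused_channels=32)


def toy_train_config(seed: int) -> TrainConfig:
    # 300 optimizer steps; the decay interval is measured against the
    # full-scale step budget, so the toy run sees a constant learning rate
    return TrainConfig(max_steps=300, seed=seed, lr_decay_every=100)


def run_toy_experiment(seed: int, bandwidth: float = 0.6) -> dict:
    """Train the toy profile on synthetic plants and evaluate the held-out split.

    Conditions: 3 species x 3 plants, 2:1 plant-level split, 4 VFPS draws of
    512 points each, 300 optimizer steps.  Returns semantic accuracy, leaf
    instance measures and the loss trend.
    """
    train_clouds, test_clouds, _ = generate_dataset(
        3, n_points=512, reps=4, seed=seed,
        base_spec=PlantSpec(points_per_organ=(300, 600)))
    network = SegmentationNetwork(toy_network_config(), seed=seed)
    best, log = train(network, train_clouds, test_clouds,
                      toy_train_config(seed), LossParams())
    network.load_state_dict(best["state"])

    accs, evals = [], []
    for cloud in test_clouds:
        out = network.forward(cloud.coords, seed=0)
        sem = predict_semantics(out.sem_logits.data)
        ins = cluster_instances(out.ins_embed.data, bandwidth=bandwidth)
        accs.append(float(np.mean(sem == cloud.sem_label)))
        evals.append(evaluate_cloud(sem, ins, assign_instance_class(sem, ins),
                                    cloud.sem_label, cloud.ins_label,
                                    6, LEAF_CLASSES))
    rep = report(evals, 6, LEAF_CLASSES)
    losses = [l["L"] for l in log]
    decile = max(1, len(losses) // 10)
    return {
        "seed": seed,
        "semantic_accuracy": float(np.mean(accs)),
        "leaf_mcov": rep.means["mCov"],
        "leaf_mwcov": rep.means["mWCov"],
        "leaf_mprec": rep.means["mPrec"],
        "leaf_mrec": rep.means["mRec"],
        "per_class_mcov": {c: v["mCov"] for c, v in rep.per_leafclass.items()},
        "loss_first_decile": float(np.mean(losses[:decile])),
        "loss_last_decile": float(np.mean(losses[-decile:])),
        "report": rep,
        "log": log,
    }
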