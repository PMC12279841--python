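"""Desk-scale experiment drivers.

The central study: train the toy detector twice on the same seeded
tiny-instance-rich synthetic dataset — once with the Gaussian-Wasserstein
EWDIoU box loss, once with a baseline family (CIoU by default) — at equal
seed, and compare mAP50 on the tiny-instance subset of a held-out
validation set.  This checks the *direction* of the claim that the
Wasserstein term helps few-pixel objects, not its full-scale magnitude.
"""

from __future__ import annotations

import logging

import numpy as np

from .boxes import LossConfig
from .metrics import tiny_subset_map50
from .model import ModelSpec, build_model
from .scenes import generate_scene, tiny_rich_config
from .train import TrainConfig, toy_train

logger = logging.getLogger(__name__)

__all__ = ["make_tiny_rich_dataset", "train_and_score", "loss_family_comparison"]


def make_tiny_rich_dataset(n_images: int, image_size: int = 160, base_seed: int = 0):
    """n seeded tiny-rich scenes (deterministic in base_seed)."""
    out = []
    for i in range(n_images):
        seed_i = int((base_seed * 100003 + i * 7919 + 13) % (2 ** 31))
        out.append(generate_scene(tiny_rich_config(image_size, seed=seed_i)))
    return out


def _loss_config(family: str) -> LossConfig:
    if family == "ewdiou":
        return LossConfig(family="ewdiou", lambda1=0.7, lambda2=0.3, M=1.0)
    return LossConfig(family=family, lambda1=1.0, lambda2=0.0)


def train_and_score(train_set, val_set, family: str, seed: int,
                    epochs: int = 18, image_size: int = 160) -> dict:
    """Train one model with the given box-loss family; return tiny-subset and
    overall mAP50 on the validation set."""
    model = build_model(ModelSpec(input_size=image_size), seed=seed)
    model, trace = toy_train(model, train_set, _loss_config(family),
                             TrainConfig(epochs=epochs, batch_size=10, seed=seed))
    imgs = np.stack([im for im, _ in val_set])
    dets = model.predict(imgs, conf_threshold=0.25, nms_iou=0.7)
    images = [(d, gts) for d, (_, gts) in zip(dets, val_set)]
    from .metrics import evaluate_dataset
    res = evaluate_dataset(images)
    return {
        "family": family,
        "seed": seed,
        "tiny_map50": tiny_subset_map50(images),
        "map50": res["map50"],
        "final_loss": trace[-1]["loss"],
    }


def loss_family_comparison(seeds=(1, 2, 3), epochs: int = 18,
                           n_train: int = 100, n_val: int = 25,
                           image_size: int = 160,
                           families=("ewdiou", "ciou"),
                           data_seed: int = 10_000) -> list[dict]:
    """Paired runs over seeds: each family trained on the identical dataset
    and weight initialization at each seed."""
    train_set = make_tiny_rich_dataset(n_train, image_size, base_seed=data_seed)
    val_set = make_tiny_rich_dataset(n_val, image_size, base_seed=data_seed + 1)
    rows = []
    for seed in seeds:
        for family in families:
            row = train_and_score(train_set, val_set, family, seed,
                                  epochs=epochs, image_size=image_size)
            logger.info("seed %d  %s  tiny mAP50 %.4f", seed, family, row["tiny_map50"])
            rows.append(row)
    return rows
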