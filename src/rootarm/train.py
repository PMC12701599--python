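"""Desk-scale training loops for the built-in backbones.

Converts synthetic scenes into (image, label) tensors and runs plain
SGD epochs over the segmentation loss, optionally with an L1 sparsity
penalty on the batch-norm scale factors (see :mod:`rootarm.pruning`).
The default optimiser settings follow the reference schedule (initial
learning rate 1e-2 decayed toward 1e-4, weight decay 5e-4, batch size 8)
scaled down to the desk problem size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["TrainSettings", "scenes_to_tensors", "train_segmentation"]


@dataclass
class TrainSettings:
    epochs: int = 20
    batch_size: int = 8
    lr: float = 1e-2
    final_lr: float = 1e-4
    weight_decay: float = 5e-4
    momentum: float = 0.9
    sparsity_lambda: float = 0.0  # L1 pressure on BN gammas
    rng_seed: int = 0


def scenes_to_tensors(scenes) -> tuple[np.ndarray, np.ndarray]:
    """Stack scenes into x (N,3,H,W) in [0,1] and integer labels (N,H,W)."""
    xs, ys = [], []
    for sc in scenes:
        xs.append(sc.image.astype(float).transpose(2, 0, 1) / 255.0)
        label = np.zeros(sc.image.shape[:2], dtype=np.int64)
        for inst in sc.instances:
            label[inst.mask.grid] = 1 if inst.class_label == "seed" else 2
        ys.append(label)
    return np.stack(xs), np.stack(ys)


def _bn_nodes(model) -> list[str]:
    return [n["name"] for n in model.nodes if n["kind"] == "bn"]


def train_segmentation(model, scenes, settings: TrainSettings,
                       loss_hook=None) -> list[float]:
    """SGD over the model's own segmentation loss; returns per-epoch losses.

    When ``settings.sparsity_lambda > 0`` the subgradient of
    ``lambda * sum |gamma|`` is added to every BN scale gradient and the
    penalty is included in the reported loss, so the recorded trace is the
    full sparsity-training objective.
    """
    x, y = scenes_to_tensors(scenes)
    rng = np.random.default_rng(settings.rng_seed)
    opt = nn.SGD(lr=settings.lr, momentum=settings.momentum,
                 weight_decay=settings.weight_decay)
    lam = settings.sparsity_lambda
    trace: list[float] = []
    n = x.shape[0]
    for epoch in range(settings.epochs):
        # geometric decay from lr to final_lr across epochs
        if settings.epochs > 1:
            frac = epoch / (settings.epochs - 1)
            opt.lr = settings.lr * (settings.final_lr / settings.lr) ** frac
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            acts, caches = model.forward(x[idx], train=True)
            loss, dlogits = model.segmentation_loss(acts["head"], y[idx])
            grads = model.backward(caches, acts, dlogits)
            if lam > 0:
                for bn in _bn_nodes(model):
                    gamma = model.params[bn]["gamma"]
                    loss += lam * np.abs(gamma).sum()
                    if bn in grads:
                        grads[bn]["gamma"] = grads[bn]["gamma"] + lam * np.sign(gamma)
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        trace.append(epoch_loss / max(n_batches, 1))
        if loss_hook is not None:
            loss_hook(epoch, trace[-1])
    model.trained = True
    return trace
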