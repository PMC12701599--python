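"""Backbone contract and the built-in tiny segmentation network.

``BackboneHandle`` is the protocol through which the distillation, pruning
and evaluation code talk to any segmentation backbone: named feature-map
taps, an instance predictor, trainable-parameter access, a declarative
graph description for complexity accounting and pruning surgery, and the
backbone's own segmentation training loss.

``TinySegNet`` is a small encoder-decoder (one pooling stage, a concat skip
connection, batch-norm everywhere, ~10^4 parameters) with a three-way
per-pixel head (background / seed / root).  Instances are formed by
connected-component labelling of the per-class probability masks, with the
component's mean probability as its confidence.  It trains on CPU on
synthetic germination scenes in minutes and is the desk-scale stand-in for
a production single-stage segmentation backbone; production backbones plug
in through the same contract via the adapter registry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from . import nn
from .complexity import ArchitectureSpec, ConvLayer, PassThrough, PoolLayer
from .maskgeom import BinaryMask
from .metrics import InstancePrediction

__all__ = [
    "BackboneHandle",
    "FeatureMap",
    "TinySegNet",
    "UntrainedModelError",
    "register_backbone",
    "get_backbone",
]

CLASS_IDS = {"background": 0, "seed": 1, "root": 2}
_EIGHT = np.ones((3, 3), dtype=bool)


class UntrainedModelError(RuntimeError):
    """Prediction requested from a model that has never been trained."""


@dataclass(frozen=True)
class FeatureMap:
    """C x H x W activations from one tapped layer."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] < 1 or v.shape[1] * v.shape[2] < 1:
            raise ValueError("feature map must be C x H x W with C,N >= 1")
        if not np.isfinite(v).all():
            raise ValueError("feature map contains non-finite activations")
        object.__setattr__(self, "values", v)

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_positions(self) -> int:
        return self.values.shape[1] * self.values.shape[2]


@runtime_checkable
class BackboneHandle(Protocol):
    def tap_ids(self) -> list[str]: ...

    def taps(self, layer_ids: Sequence[str], batch: np.ndarray) -> list[np.ndarray]: ...

    def predict_instances(self, image: np.ndarray) -> list[InstancePrediction]: ...

    def graph_description(self, input_hw: tuple[int, int]): ...


def _taps_validate(available: Sequence[str], requested: Sequence[str]) -> None:
    if len(set(requested)) != len(requested):
        raise ValueError(f"duplicate layer ids in {list(requested)}")
    unknown = [i for i in requested if i not in available]
    if unknown:
        raise KeyError(
            f"unknown layer ids {unknown}; available: {sorted(available)}"
        )


class TinySegNet:
    """Encoder-decoder segmentation net on the numpy kernel layer.

    Architecture (all convs same-padded, BN + ReLU unless noted)::

        enc1: conv3x3 (3 -> c1)
        pool: maxpool 2x2
        enc2: conv3x3 (c1 -> c2)
        up:   nearest x2
        cat:  concat(enc1, up)
        dec:  conv3x3 (c1+c2 -> c3)
        head: conv1x1 (c3 -> 3 classes), bias, no BN

    Tap ids: ``enc1``, ``enc2``, ``dec`` (the post-ReLU maps).
    """

    def __init__(self, widths: tuple[int, int, int] = (16, 32, 16),
                 rng_seed: int = 0):
        c1, c2, c3 = widths
        self.widths = (c1, c2, c3)
        rng = np.random.default_rng(rng_seed)
        self.nodes = [
            {"name": "input", "kind": "input"},
            {"name": "enc1_conv", "kind": "conv", "inputs": ["input"], "k": 3},
            {"name": "enc1_bn", "kind": "bn", "inputs": ["enc1_conv"]},
            {"name": "enc1", "kind": "relu", "inputs": ["enc1_bn"]},
            {"name": "pool", "kind": "maxpool2", "inputs": ["enc1"]},
            {"name": "enc2_conv", "kind": "conv", "inputs": ["pool"], "k": 3},
            {"name": "enc2_bn", "kind": "bn", "inputs": ["enc2_conv"]},
            {"name": "enc2", "kind": "relu", "inputs": ["enc2_bn"]},
            {"name": "up", "kind": "upsample2", "inputs": ["enc2"]},
            {"name": "cat", "kind": "concat", "inputs": ["enc1", "up"]},
            {"name": "dec_conv", "kind": "conv", "inputs": ["cat"], "k": 3},
            {"name": "dec_bn", "kind": "bn", "inputs": ["dec_conv"]},
            {"name": "dec", "kind": "relu", "inputs": ["dec_bn"]},
            {"name": "head", "kind": "conv", "inputs": ["dec"], "k": 1},
        ]
        self.params = {
            "enc1_conv": nn.init_conv(rng, 3, c1, 3),
            "enc1_bn": nn.init_bn(c1),
            "enc2_conv": nn.init_conv(rng, c1, c2, 3),
            "enc2_bn": nn.init_bn(c2),
            "dec_conv": nn.init_conv(rng, c1 + c2, c3, 3),
            "dec_bn": nn.init_bn(c3),
            "head": nn.init_conv(rng, c3, 3, 1, bias=True),
        }
        self.trained = False
        self.class_weights = np.array([1.0, 2.0, 8.0])
        self.mask_threshold = 0.5
        self.min_instance_area = 3

    # -- contract -----------------------------------------------------------

    def tap_ids(self) -> list[str]:
        return ["enc1", "enc2", "dec"]

    def taps(self, layer_ids: Sequence[str], batch: np.ndarray) -> list[np.ndarray]:
        """Feature maps (N,C,H,W) for the requested ids, in request order."""
        _taps_validate(self.tap_ids(), layer_ids)
        acts, _ = nn.graph_forward(self.nodes, self.params, batch, train=False)
        return [acts[i] for i in layer_ids]

    def forward(self, batch: np.ndarray, train: bool = False,
                update_bn_stats: bool | None = None):
        acts, caches = nn.graph_forward(self.nodes, self.params, batch,
                                        train=train,
                                        update_bn_stats=update_bn_stats)
        return acts, caches

    def backward(self, caches, acts, dlogits, extra_grads=None):
        return nn.graph_backward(self.nodes, self.params, acts, caches,
                                 dlogits, extra_grads)

    def segmentation_loss(self, logits: np.ndarray, target: np.ndarray):
        """The backbone's own training loss (weighted pixel cross-entropy)."""
        return nn.softmax_cross_entropy(logits, target, self.class_weights)

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Class probabilities (3,H,W) for one H x W x 3 uint8 image."""
        x = image.astype(float).transpose(2, 0, 1)[None] / 255.0
        acts, _ = self.forward(x, train=False)
        logits = acts["head"][0]
        e = np.exp(logits - logits.max(axis=0, keepdims=True))
        return e / e.sum(axis=0, keepdims=True)

    def predict_instances(self, image: np.ndarray,
                          image_id: str = "img") -> list[InstancePrediction]:
        """Connected-component instancing of the class-probability masks."""
        if not self.trained:
            raise UntrainedModelError(
                "TinySegNet has not been trained; call a training loop first"
            )
        probs = self.predict_probs(image)
        hard = probs.argmax(axis=0)
        preds: list[InstancePrediction] = []
        for cls, cid in (("seed", 1), ("root", 2)):
            mask = (hard == cid) & (probs[cid] >= self.mask_threshold)
            labels, n = ndimage.label(mask, structure=_EIGHT)
            for k in range(1, n + 1):
                comp = labels == k
                if comp.sum() < self.min_instance_area:
                    continue
                preds.append(
                    InstancePrediction(
                        image_id=image_id,
                        class_label=cls,
                        confidence=float(probs[cid][comp].mean()),
                        mask=BinaryMask(comp),
                        instance_id=f"{cls}-{k}",
                    )
                )
        return preds

    # -- introspection ------------------------------------------------------

    def param_count(self) -> int:
        total = 0
        for node, p in self.params.items():
            for name, arr in p.items():
                if name in ("running_mean", "running_var"):
                    continue  # buffers, not trainable
                total += arr.size
        return total

    def checksum(self) -> str:
        h = hashlib.sha256()
        for node in sorted(self.params):
            for name in sorted(self.params[node]):
                h.update(np.ascontiguousarray(self.params[node][name]))
        return h.hexdigest()

    def graph_description(self, input_hw: tuple[int, int] = (64, 64)):
        """Declarative spec plus structural metadata for pruning/complexity.

        Returns (ArchitectureSpec, info) where info carries the node graph,
        which convs carry BN, protected layers and coupling groups.  The
        spec's analytic parameter count equals the live tensor count.
        """
        h, w = input_hw
        c1, c2, c3 = (
            self.params["enc1_conv"]["W"].shape[0],
            self.params["enc2_conv"]["W"].shape[0],
            self.params["dec_conv"]["W"].shape[0],
        )
        cin_dec = self.params["dec_conv"]["W"].shape[1]
        n_cls = self.params["head"]["W"].shape[0]
        layers = [
            ConvLayer("enc1_conv", 3, c1, 3, 1, h, w, has_bias=False, has_bn=True),
            PoolLayer("pool", c1, 2, 2, h // 2, w // 2),
            ConvLayer("enc2_conv", c1, c2, 3, 1, h // 2, w // 2,
                      has_bias=False, has_bn=True),
            PassThrough("up", op="upsample"),
            PassThrough("cat", op="concat"),
            ConvLayer("dec_conv", cin_dec, c3, 3, 1, h, w,
                      has_bias=False, has_bn=True),
            ConvLayer("head", c3, n_cls, 1, 1, h, w, has_bias=True, has_bn=False),
        ]
        spec = ArchitectureSpec(name="tinysegnet", layers=layers)
        info = {
            "nodes": self.nodes,
            "bn_of_conv": {"enc1_conv": "enc1_bn", "enc2_conv": "enc2_bn",
                           "dec_conv": "dec_bn"},
            "protected": {"head"},
            "input_hw": input_hw,
        }
        return spec, info


# ---------------------------------------------------------------------------
# plug-in registry

_REGISTRY: dict[str, Callable[..., object]] = {"tinysegnet": TinySegNet}


def register_backbone(name: str, constructor: Callable[..., object]) -> None:
    _REGISTRY[name] = constructor


def get_backbone(name: str, **kwargs):
    try:
        ctor = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown backbone {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return ctor(**kwargs)
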