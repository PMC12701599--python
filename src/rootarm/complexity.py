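"""Analytic complexity accounting for convolutional segmentation networks.

Computes floating-point operation counts (FLOPs), trainable parameter
counts, serialized weight-file sizes and frames-per-second from a
declarative architecture description, using the standard closed-form
per-layer formulas:

* convolution: ``FLOPs = 2 * H * W * (C_in * K^2 + 1) * C_out`` evaluated on
  the layer's *output* spatial grid (one multiply-accumulate = 2 FLOPs),
  ``Params = C_in * K^2 * C_out`` plus bias (``C_out``) and batch-norm
  (``2 * C_out``) terms where declared;
* pooling: ``FLOPs = (H/S) * (W/S) * C_out * K^2``, no parameters;
* fully connected: ``FLOPs = 2 * n_in * n_out + n_out``,
  ``Params = n_in * n_out + n_out``.

Pass-through nodes (concat, add, upsample) carry shape only and contribute
zero FLOPs and zero parameters.

A declarative spec for the two-class YOLOv8-Seg-n network at 640x640 input
(n-scale: depth multiple 0.33, width multiple 0.25, max channels 1024,
32 prototype masks) ships with the package as
``data/yolov8_seg_n_2class.yaml``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import yaml

__all__ = [
    "ConvLayer",
    "PoolLayer",
    "FCLayer",
    "PassThrough",
    "ArchitectureSpec",
    "ComplexityReport",
    "TimingBreakdown",
    "flops_conv",
    "flops_pool",
    "flops_fc",
    "params_layer",
    "weight_file_size",
    "fps",
    "report",
    "reduction_percent",
    "retention_percent",
    "load_bundled_spec",
]


@dataclass(frozen=True)
class ConvLayer:
    """2-D convolution descriptor (transposed convs use the same accounting)."""

    name: str
    c_in: int
    c_out: int
    k: int
    stride: int
    out_h: int
    out_w: int
    has_bias: bool = False
    has_bn: bool = True

    def __post_init__(self) -> None:
        for f in ("c_in", "c_out", "k", "stride", "out_h", "out_w"):
            if getattr(self, f) <= 0:
                raise ValueError(f"conv layer {self.name!r}: {f} must be positive")


@dataclass(frozen=True)
class PoolLayer:
    name: str
    c_out: int
    k: int
    stride: int
    out_h: int
    out_w: int

    def __post_init__(self) -> None:
        for f in ("c_out", "k", "stride", "out_h", "out_w"):
            if getattr(self, f) <= 0:
                raise ValueError(f"pool layer {self.name!r}: {f} must be positive")


@dataclass(frozen=True)
class FCLayer:
    name: str
    n_in: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_in <= 0 or self.n_out <= 0:
            raise ValueError(f"fc layer {self.name!r}: sizes must be positive")


@dataclass(frozen=True)
class PassThrough:
    """Shape-only node: concat, add, upsample, input..."""

    name: str
    op: str = "pass"


Layer = ConvLayer | PoolLayer | FCLayer | PassThrough


@dataclass
class ArchitectureSpec:
    """Ordered list of layer descriptors for one network."""

    name: str
    layers: list[Layer] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        layers: list[Layer] = []
        for entry in d.get("layers", []):
            kind = entry.get("kind", "pass")
            if kind == "conv":
                layers.append(
                    ConvLayer(
                        name=entry["name"],
                        c_in=entry["c_in"],
                        c_out=entry["c_out"],
                        k=entry["k"],
                        stride=entry.get("stride", 1),
                        out_h=entry["out_h"],
                        out_w=entry["out_w"],
                        has_bias=bool(entry.get("bias", False)),
                        has_bn=bool(entry.get("bn", False)),
                    )
                )
            elif kind == "pool":
                layers.append(
                    PoolLayer(
                        name=entry["name"],
                        c_out=entry["c_out"],
                        k=entry["k"],
                        stride=entry.get("stride", 1),
                        out_h=entry["out_h"],
                        out_w=entry["out_w"],
                    )
                )
            elif kind == "fc":
                layers.append(FCLayer(entry["name"], entry["n_in"], entry["n_out"]))
            else:
                layers.append(PassThrough(entry["name"], op=kind))
        return cls(name=d.get("name", "unnamed"), layers=layers)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArchitectureSpec":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def flops_conv(layer: ConvLayer) -> int:
    """2 * H * W * (C_in * K^2 + 1) * C_out on the output grid."""
    return 2 * layer.out_h * layer.out_w * (layer.c_in * layer.k**2 + 1) * layer.c_out


def flops_pool(layer: PoolLayer) -> int:
    """(H/S) * (W/S) * C_out * K^2; descriptors store output dims directly."""
    return layer.out_h * layer.out_w * layer.c_out * layer.k**2


def flops_fc(layer: FCLayer) -> int:
    """2 * n_in * n_out + n_out."""
    return 2 * layer.n_in * layer.n_out + layer.n_out


def params_layer(layer: Layer) -> int:
    """Trainable parameter count of one layer descriptor."""
    if isinstance(layer, ConvLayer):
        p = layer.c_in * layer.k**2 * layer.c_out
        if layer.has_bias:
            p += layer.c_out
        if layer.has_bn:
            p += 2 * layer.c_out  # gamma, beta
        return p
    if isinstance(layer, FCLayer):
        return layer.n_in * layer.n_out + layer.n_out
    return 0


def flops_layer(layer: Layer) -> int:
    if isinstance(layer, ConvLayer):
        return flops_conv(layer)
    if isinstance(layer, PoolLayer):
        return flops_pool(layer)
    if isinstance(layer, FCLayer):
        return flops_fc(layer)
    return 0


def weight_file_size(total_params: int, bytes_per_param: int = 4) -> float:
    """Serialized size in MiB assuming a flat dump of parameters.

    Default 4 bytes/parameter (fp32); pass ``bytes_per_param=2`` for a
    half-precision estimate.
    """
    if total_params < 0:
        raise ValueError("total_params must be >= 0")
    return total_params * bytes_per_param / 1024**2


@dataclass(frozen=True)
class TimingBreakdown:
    preprocess_ms: float
    inference_ms: float
    postprocess_ms: float

    @property
    def total_ms(self) -> float:
        return self.preprocess_ms + self.inference_ms + self.postprocess_ms


def fps(timing: TimingBreakdown) -> float:
    """1000 / total per-frame time in milliseconds."""
    total = timing.total_ms
    if total <= 0:
        raise ValueError("total inference time must be positive")
    return 1000.0 / total


@dataclass
class ComplexityReport:
    name: str
    flops_total: int
    params_total: int
    weight_file_mb: float
    weight_file_mb_fp16: float
    per_layer: list[dict]

    @property
    def flops_g(self) -> float:
        return self.flops_total / 1e9

    @property
    def params_m(self) -> float:
        return self.params_total / 1e6

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "name": self.name,
                    "Params(M)": self.params_m,
                    "FLOPs(G)": self.flops_g,
                    "Weight File (MB)": self.weight_file_mb,
                    "Weight File fp16 (MB)": self.weight_file_mb_fp16,
                    "per_layer": self.per_layer,
                },
                f,
                indent=2,
            )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["layer", "kind", "Params", "FLOPs"])
            for row in self.per_layer:
                w.writerow([row["name"], row["kind"], row["params"], row["flops"]])
            w.writerow(["TOTAL", "", self.params_total, self.flops_total])


def report(spec: ArchitectureSpec) -> ComplexityReport:
    """Totals and per-layer breakdown; totals are exact sums of layer entries."""
    per_layer = []
    for layer in spec.layers:
        kind = type(layer).__name__
        per_layer.append(
            {
                "name": layer.name,
                "kind": kind,
                "params": params_layer(layer),
                "flops": flops_layer(layer),
            }
        )
    params_total = sum(r["params"] for r in per_layer)
    flops_total = sum(r["flops"] for r in per_layer)
    return ComplexityReport(
        name=spec.name,
        flops_total=flops_total,
        params_total=params_total,
        weight_file_mb=weight_file_size(params_total, 4),
        weight_file_mb_fp16=weight_file_size(params_total, 2),
        per_layer=per_layer,
    )


def reduction_percent(before: float, after: float) -> float:
    """Relative reduction of a complexity figure, in percent: 100*(1 - after/before)."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return 100.0 * (1.0 - after / before)


def retention_percent(before: float, after: float) -> float:
    """Fraction of a complexity figure retained after compression, in percent."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return 100.0 * after / before


def load_bundled_spec(name: str = "yolov8_seg_n_2class") -> ArchitectureSpec:
    """Load an architecture spec shipped with the package."""
    ref = resources.files("rootarm.data").joinpath(f"{name}.yaml")
    with resources.as_file(ref) as path:
        return ArchitectureSpec.from_yaml(path)


def load_compression_reference() -> dict:
    """Published complexity trajectory of the reference compression study
    (baseline and per-iteration Params/FLOPs/weight figures), as input data
    for compression-arithmetic reporting."""
    ref = resources.files("rootarm.data").joinpath("compression_reference.json")
    return json.loads(ref.read_text())
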