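"""Structured channel pruning driven by batch-norm scale factors.

Batch normalisation rescales every channel by a learnable factor
``gamma``; a channel whose ``gamma`` shrinks toward zero contributes
(almost) nothing downstream, so ``|gamma|`` serves as a channel-importance
score.  Sparsity training adds an L1 penalty ``lambda * sum |gamma|`` to
the segmentation loss to push unimportant channels toward zero; pruning
then removes the channels whose ``|gamma|`` falls below a global
quantile threshold pooled over all prunable BN layers, and a short
fine-tuning phase (with the penalty switched off) recovers accuracy.
Iterating {sparse-train, threshold, slice, fine-tune} with a small
per-iteration ratio (~10%) compresses the network progressively.

Structural rules: protected layers (output heads) are never pruned; layers
whose outputs are summed element-wise (residual adds) share the union of
their keep-masks so the graph stays valid; concatenation inputs keep their
own masks, concatenated in order; every layer always keeps at least one
channel.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .complexity import report as complexity_report
from .metrics import GroundTruthInstance, evaluate
from .train import TrainSettings, train_segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "BNLayerState",
    "PruneConfig",
    "PruningPlan",
    "bn_forward",
    "sparsity_penalty",
    "compute_threshold",
    "build_pruning_plan",
    "apply_plan",
    "iterative_prune",
]


@dataclass(frozen=True)
class BNLayerState:
    """Per-channel batch-norm state (gamma, beta, mu_B, sigma_B^2, eps)."""

    gamma: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    eps: float = 1e-5

    def __post_init__(self) -> None:
        lens = {len(np.atleast_1d(v)) for v in
                (self.gamma, self.beta, self.mu, self.sigma2)}
        if len(lens) != 1:
            raise ValueError("BN vectors must share the channel count")
        if np.any(np.atleast_1d(self.sigma2) < 0):
            raise ValueError("variance must be >= 0")
        if self.eps < 0 or np.any(np.atleast_1d(self.sigma2) + self.eps <= 0):
            raise ValueError("need eps >= 0 and sigma^2 + eps > 0")


def bn_forward(z_in: np.ndarray, state: BNLayerState) -> np.ndarray:
    """z_out = gamma * (z_in - mu_B) / sqrt(sigma_B^2 + eps) + beta."""
    z = np.asarray(z_in, dtype=float)
    return state.gamma * (z - state.mu) / np.sqrt(state.sigma2 + state.eps) + state.beta


def sparsity_penalty(gammas, lambda_: float) -> float:
    """lambda * sum over all BN scale factors of |gamma| (the L1 term
    added to the segmentation loss during sparsity training)."""
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    total = sum(float(np.abs(np.atleast_1d(g)).sum()) for g in gammas)
    return lambda_ * total


def compute_threshold(all_gammas: np.ndarray, ratio: float) -> float:
    """Global |gamma| cutoff: the ``ratio``-quantile of the pooled scores.

    Channels with ``|gamma| < threshold`` (strict) are marked prunable, so
    ties at the threshold are kept.  With n pooled values the threshold is
    the ``floor(ratio * n)``-th order statistic, which marks exactly that
    many channels when values are distinct.
    """
    pool = np.abs(np.ravel(all_gammas))
    if pool.size == 0:
        raise ValueError("empty gamma pool")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    k = int(np.floor(ratio * pool.size))
    return float(np.sort(pool)[min(k, pool.size - 1)])


@dataclass
class PruneConfig:
    lambda_: float = 1e-4
    ratio_per_iter: float = 0.10
    iterations: int = 5
    finetune_epochs: int = 20
    sparse_epochs: int = 10
    protected_layers: frozenset[str] = frozenset({"head"})
    map_drop_guard: float = 0.30  # stop early if mAP falls this far below best

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if not 0 < self.ratio_per_iter < 1:
            raise ValueError("ratio_per_iter must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class PruningPlan:
    """Keep-masks per BN layer plus the threshold that produced them."""

    keep_masks: dict[str, np.ndarray]  # bn node name -> bool mask
    threshold: float
    iteration: int = 0

    def __post_init__(self) -> None:
        for name, m in self.keep_masks.items():
            if not m.any():
                raise ValueError(f"plan would empty layer {name}")

    def n_kept(self) -> int:
        return int(sum(m.sum() for m in self.keep_masks.values()))

    def n_total(self) -> int:
        return int(sum(m.size for m in self.keep_masks.values()))

    def to_json(self, path: str | Path) -> None:
        def rle(mask: np.ndarray) -> str:
            out, run, cur = [], 0, True
            for v in mask:
                if bool(v) == cur:
                    run += 1
                else:
                    out.append(str(run))
                    cur, run = bool(v), 1
            out.append(str(run))
            return ",".join(out)  # runs of keep/drop starting with keep

        with open(path, "w") as f:
            json.dump(
                {
                    "threshold": self.threshold,
                    "iteration": self.iteration,
                    "keep_masks": {k: rle(v) for k, v in self.keep_masks.items()},
                },
                f,
                indent=2,
            )


def _coupled_groups(nodes) -> list[set[str]]:
    """BN layers whose producing convs feed a common element-wise add."""
    producers: dict[str, str] = {}  # node name -> upstream conv name
    by_name = {n["name"]: n for n in nodes}

    def upstream_conv(name: str) -> str | None:
        node = by_name[name]
        if node["kind"] == "conv":
            return name
        if node["kind"] in ("bn", "relu", "maxpool2", "upsample2"):
            return upstream_conv(node["inputs"][0])
        return None  # concat/add/input: no single producer

    groups = []
    for node in nodes:
        if node["kind"] == "add":
            convs = {upstream_conv(i) for i in node["inputs"]}
            convs.discard(None)
            if len(convs) > 1:
                groups.append(convs)
    return groups


def build_pruning_plan(model, threshold: float, config: PruneConfig,
                       iteration: int = 0) -> PruningPlan:
    """Keep-masks for every prunable BN layer under the global threshold.

    Protected layers keep all channels; add-coupled convs receive the union
    of their keep-masks; a plan that would empty a layer instead keeps that
    layer's single largest-|gamma| channel (logged).
    """
    _, info = model.graph_description()
    bn_of_conv: dict[str, str] = info["bn_of_conv"]
    protected: set[str] = set(config.protected_layers) | set(info["protected"])
    keep: dict[str, np.ndarray] = {}
    for conv, bn in bn_of_conv.items():
        gamma = model.params[bn]["gamma"]
        if conv in protected or bn in protected:
            keep[bn] = np.ones(gamma.size, dtype=bool)
            continue
        mask = np.abs(gamma) >= threshold
        if not mask.any():
            mask[int(np.argmax(np.abs(gamma)))] = True
            logger.warning(
                "layer %s: threshold would drop every channel; keeping the "
                "largest-|gamma| one", bn
            )
        keep[bn] = mask
    # union across add-coupled producers
    conv_of_bn = {bn: conv for conv, bn in bn_of_conv.items()}
    for group in _coupled_groups(model.nodes):
        bns = [bn_of_conv[c] for c in group if c in bn_of_conv]
        if len(bns) > 1:
            union = np.logical_or.reduce([keep[b] for b in bns])
            for b in bns:
                keep[b] = union.copy()
    return PruningPlan(keep_masks=keep, threshold=threshold, iteration=iteration)


def _output_masks(model, plan: PruningPlan) -> dict[str, np.ndarray]:
    """Per-node output-channel keep masks, propagated through the graph."""
    _, info = model.graph_description()
    bn_of_conv = info["bn_of_conv"]
    masks: dict[str, np.ndarray] = {}
    for node in model.nodes:
        name, kind = node["name"], node["kind"]
        if kind == "input":
            masks[name] = np.ones(3, dtype=bool)
        elif kind == "conv":
            c_out = model.params[name]["W"].shape[0]
            bn = bn_of_conv.get(name)
            masks[name] = (plan.keep_masks[bn].copy() if bn in plan.keep_masks
                           else np.ones(c_out, dtype=bool))
        elif kind in ("bn", "relu", "maxpool2", "upsample2"):
            masks[name] = masks[node["inputs"][0]]
        elif kind == "concat":
            masks[name] = np.concatenate([masks[i] for i in node["inputs"]])
        elif kind == "add":
            ms = [masks[i] for i in node["inputs"]]
            if any(len(m) != len(ms[0]) or (m != ms[0]).any() for m in ms[1:]):
                raise ValueError(
                    f"add node {name}: input masks differ; plan was not "
                    "built with coupling"
                )
            masks[name] = ms[0]
        else:
            raise ValueError(f"unknown node kind {kind!r}")
    return masks


def apply_plan(model, plan: PruningPlan):
    """Physically slice conv and BN tensors according to the plan.

    Returns a deep-copied, smaller model; the input model is untouched.
    Producer output channels, consumer input channels and all BN vectors
    (including running statistics) are sliced consistently.
    """
    for bn in plan.keep_masks:
        if bn not in model.params:
            raise ValueError(f"plan names unknown layer {bn!r}")
        if plan.keep_masks[bn].size != model.params[bn]["gamma"].size:
            raise ValueError(f"plan/model channel mismatch at {bn!r}")
    pruned = copy.deepcopy(model)
    masks = _output_masks(model, plan)
    for node in pruned.nodes:
        name, kind = node["name"], node["kind"]
        if kind == "conv":
            out_mask = masks[name]
            in_mask = masks[node["inputs"][0]]
            p = pruned.params[name]
            p["W"] = p["W"][out_mask][:, in_mask]
            if "b" in p:
                p["b"] = p["b"][out_mask]
        elif kind == "bn":
            m = masks[node["inputs"][0]]
            p = pruned.params[name]
            for key in ("gamma", "beta", "running_mean", "running_var"):
                p[key] = p[key][m]
    if hasattr(pruned, "widths"):
        pruned.widths = tuple(
            int(masks[c].sum()) for c in ("enc1_conv", "enc2_conv", "dec_conv")
            if c in pruned.params
        )
    return pruned


@dataclass
class IterationRow:
    iteration: int
    map50: float
    ap_seed: float | None
    ap_root: float | None
    params_m: float
    flops_g: float
    weight_mb: float


def _evaluate_model(model, scenes) -> tuple[float, dict]:
    preds, gts = [], []
    for sc in scenes:
        preds.extend(model.predict_instances(sc.image, image_id=sc.scene_id))
        for inst in sc.instances:
            gts.append(GroundTruthInstance(sc.scene_id, inst.class_label,
                                           inst.mask))
    res = evaluate(preds, gts)
    return res.map50, res.per_class


def iterative_prune(model, train_scenes, config: PruneConfig,
                    eval_scenes=None,
                    settings: TrainSettings | None = None):
    """Iterated {sparse-train, threshold, plan, slice, fine-tune} loop.

    Returns (models, rows): the model after every iteration (index 0 = the
    input model fine-tuned by sparsity training only) and a report table
    row per iteration with mAP@0.5 and complexity figures.  Stops early and
    returns the sequence so far if mAP collapses more than
    ``config.map_drop_guard`` below the best seen.
    """
    settings = settings or TrainSettings()
    eval_scenes = eval_scenes if eval_scenes is not None else train_scenes
    current = copy.deepcopy(model)
    models = [current]
    rows: list[IterationRow] = []

    def _row(m, it) -> IterationRow:
        spec, _ = m.graph_description()
        rep = complexity_report(spec)
        map50, per_class = _evaluate_model(m, eval_scenes)
        return IterationRow(
            iteration=it, map50=map50,
            ap_seed=per_class.get("seed"), ap_root=per_class.get("root"),
            params_m=rep.params_m, flops_g=rep.flops_g,
            weight_mb=rep.weight_file_mb,
        )

    rows.append(_row(current, 0))
    best_map = rows[0].map50
    for it in range(1, config.iterations + 1):
        sparse = TrainSettings(
            epochs=config.sparse_epochs, batch_size=settings.batch_size,
            lr=settings.lr, final_lr=settings.final_lr,
            weight_decay=settings.weight_decay, momentum=settings.momentum,
            sparsity_lambda=config.lambda_, rng_seed=settings.rng_seed + it,
        )
        train_segmentation(current, train_scenes, sparse)
        _, info = current.graph_description()
        prunable = [
            bn for conv, bn in info["bn_of_conv"].items()
            if conv not in config.protected_layers | set(info["protected"])
        ]
        pool = np.concatenate([current.params[b]["gamma"] for b in prunable])
        thr = compute_threshold(pool, config.ratio_per_iter)
        plan = build_pruning_plan(current, thr, config, iteration=it)
        current = apply_plan(current, plan)
        finetune = TrainSettings(
            epochs=config.finetune_epochs, batch_size=settings.batch_size,
            lr=settings.lr, final_lr=settings.final_lr,
            weight_decay=settings.weight_decay, momentum=settings.momentum,
            sparsity_lambda=0.0, rng_seed=settings.rng_seed + 100 + it,
        )
        train_segmentation(current, train_scenes, finetune)
        models.append(current)
        rows.append(_row(current, it))
        best_map = max(best_map, rows[-1].map50)
        if rows[-1].map50 < best_map - config.map_drop_guard:
            logger.warning("mAP collapsed at iteration %d; stopping early", it)
            break
    return models, rows


def rows_to_csv(rows, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["Number of Iterations", "mAP@0.5(%)", "AP_seed(%)",
                    "AP_root(%)", "Params(M)", "FLOPs(G)", "Weight File(MB)"])
        for r in rows:
            w.writerow([
                r.iteration, f"{100 * r.map50:.1f}",
                "" if r.ap_seed is None else f"{100 * r.ap_seed:.1f}",
                "" if r.ap_root is None else f"{100 * r.ap_root:.1f}",
                f"{r.params_m:.6f}", f"{r.flops_g:.6f}", f"{r.weight_mb:.4f}",
            ])
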