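"""Channel-wise feature distillation between segmentation backbones.

A trained, frozen teacher and a smaller student expose intermediate
feature maps at paired hint/guidance layers.  Each channel's activations
are softened into a probability distribution over spatial positions with a
temperature-``T`` softmax, and the student is trained to match the
teacher's per-channel distributions under KL divergence:

    Loss_CWD = (T^2 / C) * sum_c sum_i phi(y^T_{c,i}) *
               log[ phi(y^T_{c,i}) / phi(y^S_{c,i}) ]

where ``phi`` normalises over the ``N = W * H`` spatial positions of one
channel.  Because KL is asymmetric the student concentrates on the
teacher's high-activation (foreground) regions and pays little for
mismatched background.  The total objective is the student's own
segmentation loss plus ``alpha`` times the distillation term
(``alpha = 1`` by default, matching the reference setting); the
temperature default is the neutral ``T = 1``.

When teacher and student widths differ, a learnable 1x1 convolution
(the channel adapter) maps student channels onto the teacher's before the
KL term is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import FeatureMap
from .train import TrainSettings, scenes_to_tensors

__all__ = [
    "DistillConfig",
    "ChannelAdapter",
    "channel_softmax",
    "cwd_loss",
    "adapt_channels",
    "total_distill_loss",
    "run_distillation",
    "LAYER_PRESETS",
]

# hint/guidance layer index sets reported for the reference YOLOv8-Seg
# backbone; stored as named presets because the indices are meaningful only
# for that specific backbone's layer numbering
LAYER_PRESETS: dict[str, tuple[str, ...]] = {
    "yolov8-seg-3layer": ("15", "18", "21"),
    "yolov8-seg-6layer": ("6", "8", "12", "15", "18", "21"),
    "yolov8-seg-8layer": ("2", "4", "6", "8", "12", "15", "18", "21"),
}


@dataclass(frozen=True)
class DistillConfig:
    """Hint/guidance layer pairing plus temperature and loss weight."""

    teacher_layers: tuple[str, ...]
    student_layers: tuple[str, ...]
    temperature: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not self.teacher_layers:
            raise ValueError("at least one distillation layer is required")
        if len(self.teacher_layers) != len(self.student_layers):
            raise ValueError("teacher and student layer lists must pair up")
        for ids in (self.teacher_layers, self.student_layers):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate layer ids in {ids}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class ChannelAdapter:
    """Learnable 1x1 convolution mapping C_S student channels to C_T."""

    weights: np.ndarray  # (C_T, C_S)

    @classmethod
    def identity(cls, channels: int) -> "ChannelAdapter":
        return cls(np.eye(channels))

    @classmethod
    def random(cls, c_teacher: int, c_student: int,
               rng: np.random.Generator) -> "ChannelAdapter":
        return cls(rng.normal(0, np.sqrt(1.0 / c_student), (c_teacher, c_student)))

    @property
    def c_in(self) -> int:
        return self.weights.shape[1]

    @property
    def c_out(self) -> int:
        return self.weights.shape[0]


def _softmax_rows(z: np.ndarray, temperature: float) -> np.ndarray:
    """Row-wise softmax with max subtraction; z is (C, N)."""
    zt = z / temperature
    zt = zt - zt.max(axis=1, keepdims=True)
    e = np.exp(zt)
    return e / e.sum(axis=1, keepdims=True)


def _as_cn(fm: FeatureMap | np.ndarray) -> np.ndarray:
    v = fm.values if isinstance(fm, FeatureMap) else np.asarray(fm, dtype=float)
    if v.ndim == 3:
        v = v.reshape(v.shape[0], -1)
    if not np.isfinite(v).all():
        raise ValueError("non-finite activation in feature map")
    return v


def channel_softmax(fm: FeatureMap, temperature: float = 1.0) -> FeatureMap:
    """Per-channel spatial softmax; every channel sums to one."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    v = fm.values
    probs = _softmax_rows(v.reshape(v.shape[0], -1), temperature)
    return FeatureMap(probs.reshape(v.shape))


def cwd_loss(teacher_fm: FeatureMap | np.ndarray,
             student_fm: FeatureMap | np.ndarray,
             temperature: float = 1.0,
             layer_name: str = "?") -> float:
    """Channel-wise KL distillation loss between two matched feature maps.

    Computed as log-softmax differences for numerical safety.  The teacher
    side is a constant (no gradient flows through it).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    t = _as_cn(teacher_fm)
    s = _as_cn(student_fm)
    if t.shape != s.shape:
        raise ValueError(
            f"layer {layer_name}: teacher {t.shape} vs student {s.shape} "
            "after adaptation"
        )
    c = t.shape[0]
    tt, ss = t / temperature, s / temperature
    log_pt = tt - tt.max(axis=1, keepdims=True)
    log_pt = log_pt - np.log(np.exp(log_pt).sum(axis=1, keepdims=True))
    log_ps = ss - ss.max(axis=1, keepdims=True)
    log_ps = log_ps - np.log(np.exp(log_ps).sum(axis=1, keepdims=True))
    pt = np.exp(log_pt)
    return float(temperature**2 / c * (pt * (log_pt - log_ps)).sum())


def cwd_grad_wrt_student(teacher_fm, student_fm, temperature: float = 1.0) -> np.ndarray:
    """d Loss_CWD / d y^S, shape (C, N): (T/C) * (phi(y^S) - phi(y^T))."""
    t = _as_cn(teacher_fm)
    s = _as_cn(student_fm)
    pt = _softmax_rows(t, temperature)
    ps = _softmax_rows(s, temperature)
    return (temperature / t.shape[0]) * (ps - pt)


def adapt_channels(student_fm: FeatureMap, adapter: ChannelAdapter) -> FeatureMap:
    """Apply the 1x1 channel adapter; spatial layout is untouched."""
    v = student_fm.values
    if v.shape[0] != adapter.c_in:
        raise ValueError(
            f"adapter expects {adapter.c_in} input channels, got {v.shape[0]}"
        )
    out = np.tensordot(adapter.weights, v, axes=([1], [0]))
    return FeatureMap(out)


def total_distill_loss(seg_loss: float, cwd: float, alpha: float = 1.0) -> float:
    """Loss_Distillation = Loss_Segment + alpha * Loss_CWD."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not (np.isfinite(seg_loss) and np.isfinite(cwd)):
        raise ValueError("losses must be finite")
    return seg_loss + alpha * cwd


@dataclass
class DistillResult:
    student: object
    adapters: dict[str, ChannelAdapter]
    loss_trace: list[dict]  # per-epoch {total, seg, cwd}


def run_distillation(teacher, student, config: DistillConfig, scenes,
                     settings: TrainSettings | None = None) -> DistillResult:
    """Train the student under segmentation + channel-wise KL losses.

    The teacher runs in inference mode throughout and its parameters are
    never touched.  One channel adapter per layer pair is created lazily
    (identity-shaped random init) and trained jointly with the student.
    Seeded and reproducible via ``settings.rng_seed``.
    """
    settings = settings or TrainSettings(epochs=5)
    for ids, net in ((config.teacher_layers, teacher),
                     (config.student_layers, student)):
        available = net.tap_ids()
        missing = [i for i in ids if i not in available]
        if missing:
            raise KeyError(
                f"layer ids {missing} not exposed; available: {available}"
            )

    x, y = scenes_to_tensors(scenes)
    rng = np.random.default_rng(settings.rng_seed)
    opt = nn.SGD(lr=settings.lr, momentum=settings.momentum,
                 weight_decay=settings.weight_decay)
    adapters: dict[str, ChannelAdapter] = {}
    adapter_vel: dict[str, np.ndarray] = {}
    trace: list[dict] = []
    n = x.shape[0]

    for epoch in range(settings.epochs):
        if settings.epochs > 1:
            frac = epoch / (settings.epochs - 1)
            opt.lr = settings.lr * (settings.final_lr / settings.lr) ** frac
        order = rng.permutation(n)
        sums = {"total": 0.0, "seg": 0.0, "cwd": 0.0}
        n_batches = 0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            xb, yb = x[idx], y[idx]
            # teacher taps use batch statistics (running buffers untouched)
            # so both networks' channel distributions are normalised the
            # same way; parameters stay frozen either way
            t_acts, _ = teacher.forward(xb, train=True, update_bn_stats=False)
            s_acts, s_caches = student.forward(xb, train=True)
            seg_loss, dlogits = student.segmentation_loss(s_acts["head"], yb)

            batch_cwd = 0.0
            extra: dict[str, np.ndarray] = {}
            adapter_grads: dict[str, np.ndarray] = {}
            for t_id, s_id in zip(config.teacher_layers, config.student_layers):
                t_map = t_acts[t_id]  # (B, C_T, H, W)
                s_map = s_acts[s_id]  # (B, C_S, H, W)
                c_t, c_s = t_map.shape[1], s_map.shape[1]
                if s_id not in adapters:
                    adapters[s_id] = (
                        ChannelAdapter.identity(c_s) if c_s == c_t
                        else ChannelAdapter.random(c_t, c_s, rng)
                    )
                Wa = adapters[s_id].weights
                dWa = np.zeros_like(Wa)
                d_s = np.zeros_like(s_map)
                bsz = xb.shape[0]
                for bi in range(bsz):
                    sv = s_map[bi].reshape(c_s, -1)
                    tv = t_map[bi].reshape(c_t, -1)
                    adapted = Wa @ sv
                    batch_cwd += cwd_loss(tv, adapted, config.temperature,
                                          layer_name=s_id) / bsz
                    g_ad = cwd_grad_wrt_student(tv, adapted,
                                                config.temperature) / bsz
                    dWa += g_ad @ sv.T
                    d_s[bi] = (Wa.T @ g_ad).reshape(s_map[bi].shape)
                adapter_grads[s_id] = config.alpha * dWa
                extra[s_id] = config.alpha * d_s

            total = total_distill_loss(seg_loss, batch_cwd, config.alpha)
            grads = student.backward(s_caches, s_acts, dlogits,
                                     extra_grads=extra)
            opt.step(student.params, grads)
            for s_id, g in adapter_grads.items():
                v = adapter_vel.get(s_id)
                v = g if v is None else settings.momentum * v + g
                adapter_vel[s_id] = v
                adapters[s_id].weights -= opt.lr * v
            sums["total"] += total
            sums["seg"] += seg_loss
            sums["cwd"] += batch_cwd
            n_batches += 1
        trace.append({k: v / max(n_batches, 1) for k, v in sums.items()})
    student.trained = True
    return DistillResult(student=student, adapters=adapters, loss_trace=trace)
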