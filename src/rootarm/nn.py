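"""Minimal CPU neural-network kernels for the built-in segmentation nets.

Implements forward and backward passes for the handful of layer kinds the
desk-scale backbones need: same-padded 2-D convolution (stride 1 or 2),
batch normalisation with running statistics, ReLU, 2x2 max pooling,
nearest-neighbour 2x upsampling, channel concatenation and element-wise
addition, plus per-pixel softmax cross-entropy and plain SGD with momentum.

Everything operates on float64 NCHW arrays.  The layer graph is a list of
topologically ordered node dicts ``{name, kind, inputs, ...}``; parameters
live in a flat ``{node name: {array name: ndarray}}`` dict so that pruning
surgery can slice them in place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "bn_forward_train",
    "bn_backward",
    "bn_forward_eval",
    "graph_forward",
    "graph_backward",
    "softmax_cross_entropy",
    "SGD",
    "init_conv",
    "init_bn",
]


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray | None,
                   stride: int = 1) -> np.ndarray:
    """Same-padded convolution; x (N,C,H,W), W (Cout,Cin,K,K)."""
    k = W.shape[2]
    p = k // 2
    xp = _pad(x, p)
    n, c, hp, wp = xp.shape
    h_out = (x.shape[2] + 2 * p - k) // stride + 1
    w_out = (x.shape[3] + 2 * p - k) // stride + 1
    out = np.zeros((n, W.shape[0], h_out, w_out))
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i : i + h_out * stride : stride,
                       j : j + w_out * stride : stride]
            out += np.einsum("nchw,oc->nohw", patch, W[:, :, i, j],
                             optimize=True)
    if b is not None:
        out += b[None, :, None, None]
    return out


def conv2d_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray,
                    stride: int = 1, has_bias: bool = True):
    """Returns (dx, dW, db); db is None when has_bias is False."""
    k = W.shape[2]
    p = k // 2
    xp = _pad(x, p)
    h_out, w_out = dout.shape[2], dout.shape[3]
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i : i + h_out * stride : stride,
                       j : j + w_out * stride : stride]
            dW[:, :, i, j] = np.einsum("nohw,nchw->oc", dout, patch,
                                       optimize=True)
            dxp[:, :, i : i + h_out * stride : stride,
                j : j + w_out * stride : stride] += np.einsum(
                "nohw,oc->nchw", dout, W[:, :, i, j], optimize=True)
    dx = dxp[:, :, p : p + x.shape[2], p : p + x.shape[3]] if p else dxp
    db = dout.sum(axis=(0, 2, 3)) if has_bias else None
    return dx, dW, db


def bn_forward_train(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                     eps: float = 1e-5):
    """Batch statistics over (N, H, W); returns (y, cache)."""
    mu = x.mean(axis=(0, 2, 3))
    var = x.var(axis=(0, 2, 3))
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y, (xhat, inv, gamma)


def bn_backward(dout: np.ndarray, cache):
    xhat, inv, gamma = cache
    n = dout.shape[0] * dout.shape[2] * dout.shape[3]
    dgamma = (dout * xhat).sum(axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    dxhat = dout * gamma[None, :, None, None]
    dx = (inv[None, :, None, None] / n) * (
        n * dxhat
        - dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
    )
    return dx, dgamma, dbeta


def bn_forward_eval(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                    mu: np.ndarray, var: np.ndarray, eps: float = 1e-5):
    inv = 1.0 / np.sqrt(var + eps)
    return (gamma * inv)[None, :, None, None] * (
        x - mu[None, :, None, None]
    ) + beta[None, :, None, None]


def maxpool2_forward(x: np.ndarray):
    """2x2/stride-2 max pool; gradient goes to the first argmax per window."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xr = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    idx, shape = cache
    n, c, h, w = shape
    h2, w2 = h // 2, w // 2
    dflat = np.zeros((n, c, h2, w2, 4))
    np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(shape)
    dx[:, :, : 2 * h2, : 2 * w2] = (
        dflat.reshape(n, c, h2, w2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, 2 * h2, 2 * w2)
    )
    return dx


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray,
                          class_weights: np.ndarray | None = None):
    """Per-pixel cross entropy; logits (N,Q,H,W), target (N,H,W) int.

    Returns (mean loss, dlogits).  ``class_weights`` rebalances rare
    foreground classes; the loss is normalised by the total weight so its
    scale is comparable across weightings.
    """
    n, q, h, w = logits.shape
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    probs = e / e.sum(axis=1, keepdims=True)
    onehot = np.eye(q)[target].transpose(0, 3, 1, 2)
    if class_weights is None:
        wpix = np.ones((n, h, w))
    else:
        wpix = np.asarray(class_weights)[target]
    total_w = wpix.sum()
    logp = np.log(np.clip(probs, 1e-12, None))
    loss = -(wpix * (onehot * logp).sum(axis=1)).sum() / total_w
    dlogits = (probs - onehot) * wpix[:, None, :, :] / total_w
    return loss, dlogits


def init_conv(rng: np.random.Generator, c_in: int, c_out: int, k: int,
              bias: bool = False) -> dict:
    """He-normal initialisation."""
    std = np.sqrt(2.0 / (c_in * k * k))
    p = {"W": rng.normal(0, std, (c_out, c_in, k, k))}
    if bias:
        p["b"] = np.zeros(c_out)
    return p


def init_bn(c: int) -> dict:
    return {
        "gamma": np.ones(c),
        "beta": np.zeros(c),
        "running_mean": np.zeros(c),
        "running_var": np.ones(c),
    }


def graph_forward(nodes, params, x: np.ndarray, train: bool = False,
                  bn_momentum: float = 0.1, update_bn_stats: bool | None = None):
    """Run the node graph on batch x; returns (activations, caches).

    ``activations[name]`` is each node's output; caches hold whatever the
    matching backward pass needs.  In training mode BN uses batch statistics
    and (unless ``update_bn_stats`` is False) updates the running ones in
    place; ``train=True, update_bn_stats=False`` gives batch-statistic
    features from a frozen network, which keeps a teacher's tapped
    distributions comparable with a training student's.
    """
    if update_bn_stats is None:
        update_bn_stats = train
    acts: dict[str, np.ndarray] = {}
    caches: dict[str, object] = {}
    for node in nodes:
        name, kind = node["name"], node["kind"]
        ins = [acts[i] for i in node.get("inputs", [])]
        if kind == "input":
            acts[name] = x
        elif kind == "conv":
            p = params[name]
            acts[name] = conv2d_forward(ins[0], p["W"], p.get("b"),
                                        node.get("stride", 1))
            caches[name] = ins[0]
        elif kind == "bn":
            p = params[name]
            if train:
                y, cache = bn_forward_train(ins[0], p["gamma"], p["beta"])
                if update_bn_stats:
                    mu = ins[0].mean(axis=(0, 2, 3))
                    var = ins[0].var(axis=(0, 2, 3))
                    p["running_mean"] *= 1 - bn_momentum
                    p["running_mean"] += bn_momentum * mu
                    p["running_var"] *= 1 - bn_momentum
                    p["running_var"] += bn_momentum * var
                acts[name] = y
                caches[name] = cache
            else:
                acts[name] = bn_forward_eval(
                    ins[0], p["gamma"], p["beta"],
                    p["running_mean"], p["running_var"]
                )
        elif kind == "relu":
            acts[name] = np.maximum(ins[0], 0)
            caches[name] = acts[name] > 0
        elif kind == "maxpool2":
            acts[name], caches[name] = maxpool2_forward(ins[0])
        elif kind == "upsample2":
            acts[name] = upsample2_forward(ins[0])
        elif kind == "concat":
            acts[name] = np.concatenate(ins, axis=1)
            caches[name] = [a.shape[1] for a in ins]
        elif kind == "add":
            acts[name] = sum(ins)
        else:
            raise ValueError(f"unknown node kind {kind!r}")
    return acts, caches


def graph_backward(nodes, params, acts, caches, dout: np.ndarray,
                   extra_grads: dict[str, np.ndarray] | None = None):
    """Reverse-mode sweep; dout is the gradient at the last node's output.

    ``extra_grads`` injects additional gradients at named intermediate nodes
    (used for feature-distillation losses on tapped layers).  Returns a
    ``{node: {param: grad}}`` dict for conv and bn nodes.
    """
    grads: dict[str, dict[str, np.ndarray]] = {}
    dacc: dict[str, np.ndarray] = {nodes[-1]["name"]: dout}
    if extra_grads:
        for k, g in extra_grads.items():
            dacc[k] = dacc.get(k, 0) + g
    for node in reversed(nodes):
        name, kind = node["name"], node["kind"]
        if name not in dacc:
            continue
        d = dacc.pop(name)
        ins = node.get("inputs", [])
        if kind == "input":
            continue
        if kind == "conv":
            p = params[name]
            dx, dW, db = conv2d_backward(caches[name], p["W"], d,
                                         node.get("stride", 1),
                                         has_bias="b" in p)
            grads[name] = {"W": dW}
            if db is not None:
                grads[name]["b"] = db
        elif kind == "bn":
            dx, dgamma, dbeta = bn_backward(d, caches[name])
            grads[name] = {"gamma": dgamma, "beta": dbeta}
        elif kind == "relu":
            dx = d * caches[name]
        elif kind == "maxpool2":
            dx = maxpool2_backward(d, caches[name])
        elif kind == "upsample2":
            dx = upsample2_backward(d)
        elif kind == "concat":
            splits = np.cumsum(caches[name])[:-1]
            parts = np.split(d, splits, axis=1)
            for i, part in zip(ins, parts):
                dacc[i] = dacc.get(i, 0) + part
            continue
        elif kind == "add":
            for i in ins:
                dacc[i] = dacc.get(i, 0) + d
            continue
        dacc[ins[0]] = dacc.get(ins[0], 0) + dx
    return grads


class SGD:
    """Plain SGD with momentum and decoupled weight decay."""

    def __init__(self, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel: dict[tuple[str, str], np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> None:
        for node, g in grads.items():
            for pname, grad in g.items():
                key = (node, pname)
                p = params[node][pname]
                if self.weight_decay and pname == "W":
                    grad = grad + self.weight_decay * p
                v = self._vel.get(key)
                v = grad if v is None else self.momentum * v + grad
                self._vel[key] = v
                p -= self.lr * v
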