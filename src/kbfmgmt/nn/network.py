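"""Sequential network container, Adam optimizer and the binary loss."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .layers import Layer, Param

__all__ = ["Sequential", "Adam", "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> Tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on raw logits.

    Returns the mean loss and its gradient with respect to the logits.
    """
    z = np.asarray(logits, dtype=np.float64).reshape(-1)
    y = np.asarray(targets, dtype=np.float64).reshape(-1)
    if z.shape != y.shape:
        raise ValueError("logits and targets must have equal length")
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).reshape(np.asarray(logits).shape)
    return loss, grad.astype(np.float32)


class Sequential:
    """A feed-forward stack of layers with manual reverse-mode gradients."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers: List[Layer] = list(layers)

    def parameters(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Backpropagate ``gy`` (d loss / d output); returns d loss / d input.

        Must follow a ``forward(..., train=True)`` call; parameter gradients
        accumulate into ``Param.grad``.
        """
        g = np.asarray(gy, dtype=np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Gradient of the summed scalar output with respect to the input.

        Runs a train-mode forward purely to populate the backward caches, but
        batch statistics are *not* used: batch-norm layers are temporarily
        pinned to their running estimates so the result matches the
        evaluation-mode function the classifier actually computes.
        """
        from .layers import BatchNorm

        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        saved = [(l.running_mean.copy(), l.running_var.copy(),
                  l.momentum) for l in bns]
        grads = [p.grad.copy() for p in self.parameters()]
        try:
            for l in bns:
                l.momentum = 0.0  # keep running stats untouched

            out = np.asarray(x, dtype=np.float32)
            for layer in self.layers:
                if isinstance(layer, BatchNorm):
                    # eval-statistics forward that still fills the cache
                    axes = (0,) + tuple(range(2, 2 + layer.dims))
                    cs = (1, layer.channels) + (1,) * layer.dims
                    invstd = 1.0 / np.sqrt(layer.running_var + layer.eps)
                    xhat = (out - layer.running_mean.reshape(cs)) * invstd.reshape(cs)
                    m = out.size // layer.channels
                    layer._cache = (xhat, invstd, m, axes)
                    out = (layer.gamma.value.reshape(cs) * xhat
                           + layer.beta.value.reshape(cs)).astype(np.float32)
                else:
                    out = layer.forward(out, train=True)
            g = np.ones_like(out)
            for layer in reversed(self.layers):
                if isinstance(layer, BatchNorm):
                    # in eval mode the normalisation is an affine map per
                    # channel: dx = gy * gamma * invstd
                    xhat, invstd, m, axes = layer._cache
                    cs = (1, layer.channels) + (1,) * layer.dims
                    g = g * layer.gamma.value.reshape(cs) * invstd.reshape(cs)
                    g = g.astype(np.float32)
                else:
                    g = layer.backward(g)
        finally:
            for l, (rm, rv, mom) in zip(bns, saved):
                l.running_mean, l.running_var, l.momentum = rm, rv, mom
            for p, g0 in zip(self.parameters(), grads):
                p.grad[...] = g0
        return g

    # ---- checkpointing -------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for p in layer.params():
                state[f"{i}.{p.name}"] = p.value
            if hasattr(layer, "running_mean"):
                state[f"{i}.bn.running_mean"] = layer.running_mean
                state[f"{i}.bn.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for p in layer.params():
                p.value = np.asarray(state[f"{i}.{p.name}"], dtype=np.float32)
                p.grad = np.zeros_like(p.value)
            if hasattr(layer, "running_mean"):
                layer.running_mean = np.asarray(
                    state[f"{i}.bn.running_mean"], dtype=np.float32)
                layer.running_var = np.asarray(
                    state[f"{i}.bn.running_var"], dtype=np.float32)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


class Adam:
    """Adam optimizer (Kingma & Ba) over a parameter list."""

    def __init__(self, params: Sequence[Param], lr: float = 5e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
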