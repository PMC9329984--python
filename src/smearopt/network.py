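"""Lightweight CNN engine: forward/backward passes over a LayerPlan.

Realizes an :class:`~smearopt.architecture.LayerPlan` as an executable
network backed purely by numpy.  Convolutions are evaluated as nine
BLAS matrix products (one per 3x3 kernel offset), which keeps desk-scale
training fast on a single core.  Activations use the NCHW layout in
float32 (configurable for e.g. float64 gradient checking).

The engine implements exactly what the block-structured classifier needs:
same-padded stride-1 convolution, batch normalization with running
statistics, ReLU, 2x2 max/average pooling, global average pooling,
inverted dropout, a fully-connected head and a fused softmax +
cross-entropy loss.
"""

from __future__ import annotations

import numpy as np

from .architecture import LayerPlan

__all__ = ["Network", "realize_network", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Layer:
    """Base: parameter-free, shape-preserving layer."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # weights subject to the L2 penalty (conv/FC kernels only)
    def penalized(self) -> list[str]:
        return []


class _Conv2D(_Layer):
    def __init__(self, in_ch, out_ch, kernel, padding, rng, dtype):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He fan-in
        self.k, self.pad = kernel, padding
        self.params = {
            "W": (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale).astype(dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }

    def penalized(self):
        return ["W"]

    def forward(self, x, training):
        W, b = self.params["W"], self.params["b"]
        N, Ci, H, Wd = x.shape
        p, k = self.pad, self.k
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        Co = W.shape[0]
        out = np.zeros((Co, N * H * Wd), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                xs = xpad[:, :, ki : ki + H, kj : kj + Wd]
                xs_flat = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(Ci, -1)
                out += W[:, :, ki, kj] @ xs_flat
        self._cache = (xpad, x.shape)
        out = out.reshape(Co, N, H, Wd).transpose(1, 0, 2, 3)
        return out + b[None, :, None, None]

    def backward(self, dout):
        W = self.params["W"]
        xpad, xshape = self._cache
        N, Ci, H, Wd = xshape
        p, k = self.pad, self.k
        Co = W.shape[0]
        dout_flat = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(Co, -1)
        dW = np.zeros_like(W)
        dxpad = np.zeros_like(xpad)
        for ki in range(k):
            for kj in range(k):
                xs = xpad[:, :, ki : ki + H, kj : kj + Wd]
                xs_flat = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(Ci, -1)
                dW[:, :, ki, kj] = dout_flat @ xs_flat.T
                dxs = (W[:, :, ki, kj].T @ dout_flat).reshape(Ci, N, H, Wd)
                dxpad[:, :, ki : ki + H, kj : kj + Wd] += dxs.transpose(1, 0, 2, 3)
        self.grads = {"W": dW, "b": dout.sum(axis=(0, 2, 3))}
        if p:
            return dxpad[:, :, p : p + H, p : p + Wd]
        return dxpad


class _BatchNorm2D(_Layer):
    def __init__(self, channels, decay, dtype, eps=1e-5):
        super().__init__()
        self.decay, self.eps = decay, eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, training):
        g, b = self.params["gamma"], self.params["beta"]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if getattr(self, "_accumulate", False):
                self._sum_mean = self._sum_mean + mean
                self._sum_var = self._sum_var + var
                self._n_batches += 1
            else:
                self.running_mean = ((1 - self.decay) * self.running_mean
                                     + self.decay * mean).astype(x.dtype)
                self.running_var = ((1 - self.decay) * self.running_var
                                    + self.decay * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv) if training else None
        return g[None, :, None, None] * xhat + b[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        g = self.params["gamma"]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dbeta = dout.sum(axis=(0, 2, 3))
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads = {"gamma": dgamma, "beta": dbeta}
        coeff = (g * inv / m)[None, :, None, None]
        dx = coeff * (
            m * dout
            - dbeta[None, :, None, None]
            - xhat * dgamma[None, :, None, None]
        )
        return dx.astype(dout.dtype)


class _ReLU(_Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _Pool2(_Layer):
    def __init__(self, mode):
        super().__init__()
        self.mode = mode  # "max" | "avg"

    def forward(self, x, training):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        if self.mode == "max":
            out = xr.max(axis=(3, 5))
            mask = xr == out[:, :, :, None, :, None]
            # split gradient evenly across ties for a symmetric subgradient
            self._cache = mask / mask.sum(axis=(3, 5), keepdims=True)
        else:
            out = xr.mean(axis=(3, 5))
            self._cache = None
        self._shape = x.shape
        return out

    def backward(self, dout):
        N, C, H, W = self._shape
        d = dout[:, :, :, None, :, None]
        if self.mode == "max":
            dx = (self._cache * d).reshape(N, C, H, W)
        else:
            dx = np.broadcast_to(d / 4.0, (N, C, H // 2, 2, W // 2, 2)).reshape(
                N, C, H, W
            )
        return np.ascontiguousarray(dx)


class _GlobalAvgPool(_Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        N, C, H, W = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (H * W), self._shape
        ).astype(dout.dtype)


class _Dropout(_Layer):
    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Dense(_Layer):
    def __init__(self, in_f, out_f, rng, dtype):
        super().__init__()
        scale = np.sqrt(2.0 / in_f)
        self.params = {
            "W": (rng.standard_normal((in_f, out_f)) * scale).astype(dtype),
            "b": np.zeros(out_f, dtype=dtype),
        }

    def penalized(self):
        return ["W"]

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class Network:
    """Executable realization of a :class:`LayerPlan`.

    The trailing softmax descriptor is folded into the loss; ``forward``
    returns logits and ``predict_proba`` applies the softmax.
    """

    def __init__(self, plan: LayerPlan, rng=None, bn_decay: float = 0.1,
                 dtype=np.float32):
        rng = np.random.default_rng(rng)
        self.plan = plan
        self.dtype = dtype
        self.layers: list[_Layer] = []
        self._dropout_rng = rng
        for spec in plan.layers:
            a = spec.attrs
            if spec.kind == "convolution":
                self.layers.append(
                    _Conv2D(a["in_channels"], a["filters"], a["kernel"],
                            a["padding"], rng, dtype)
                )
            elif spec.kind == "batch_norm":
                self.layers.append(_BatchNorm2D(a["channels"], bn_decay, dtype))
            elif spec.kind == "relu":
                self.layers.append(_ReLU())
            elif spec.kind == "max_pool":
                self.layers.append(_Pool2("max"))
            elif spec.kind == "average_pool":
                self.layers.append(_Pool2("avg"))
            elif spec.kind == "global_average_pool":
                self.layers.append(_GlobalAvgPool())
            elif spec.kind == "dropout":
                self.layers.append(_Dropout(a["p"], rng))
            elif spec.kind == "fully_connected":
                self.layers.append(
                    _Dense(a["in_features"], a["out_features"], rng, dtype)
                )
            elif spec.kind == "softmax":
                pass  # fused into the loss / predict_proba
            else:  # pragma: no cover - plan validation catches this
                raise ValueError(f"unsupported layer kind {spec.kind!r}")

    # ---- parameter access -------------------------------------------------
    def named_parameters(self):
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                yield f"layer{i}.{name}", layer, name, arr

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {key: arr.copy() for key, _, _, arr in self.named_parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm2D):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name, arr in self.named_parameters():
            layer.params[name] = state[key].astype(self.dtype).copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm2D):
                layer.running_mean = state[f"layer{i}.running_mean"].astype(self.dtype).copy()
                layer.running_var = state[f"layer{i}.running_var"].astype(self.dtype).copy()

    # ---- execution --------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def finalize_bn_statistics(self, x: np.ndarray, batch_size: int = 128) -> None:
        """Replace batch-norm running statistics with population statistics.

        Averages per-mini-batch means and variances over a full pass of
        the (training) data, the way population-statistics finalization is
        done after SGD training; inference then sees statistics matched to
        the final weights instead of a decayed running estimate.
        """
        bns = [l for l in self.layers if isinstance(l, _BatchNorm2D)]
        if not bns:
            return
        for bn in bns:
            bn._accumulate = True
            bn._sum_mean = 0.0
            bn._sum_var = 0.0
            bn._n_batches = 0
        x = np.asarray(x, dtype=self.dtype)
        for start in range(0, x.shape[0], batch_size):
            out = x[start : start + batch_size]
            for layer in self.layers:
                if isinstance(layer, _Dropout):
                    out = layer.forward(out, training=False)
                else:
                    out = layer.forward(out, training=True)
        for bn in bns:
            if bn._n_batches:
                bn.running_mean = (bn._sum_mean / bn._n_batches).astype(self.dtype)
                bn.running_var = (bn._sum_var / bn._n_batches).astype(self.dtype)
            bn._accumulate = False

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        probs = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size], training=False)
            probs.append(softmax(logits))
        return np.concatenate(probs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def loss_and_gradients(
        self, x: np.ndarray, y: np.ndarray, regularization: float = 0.0
    ) -> tuple[float, float]:
        """One fused forward/backward pass on a mini-batch.

        Returns (regularized loss, batch accuracy).  Gradients — including
        the L2 term on penalized weights — are left on each layer's
        ``grads`` dict for the optimizer to consume.
        """
        logits = self.forward(x, training=True)
        N = logits.shape[0]
        p = softmax(logits)
        eps = np.finfo(logits.dtype).tiny
        data_loss = -float(np.mean(np.log(p[np.arange(N), y] + eps)))
        acc = float(np.mean(p.argmax(axis=1) == y))

        penalty = 0.0
        for layer in self.layers:
            for name in layer.penalized():
                w = layer.params[name]
                penalty += 0.5 * float(np.sum(w.astype(np.float64) ** 2))
        loss = data_loss + regularization * penalty

        dlogits = (p - np.eye(logits.shape[1], dtype=p.dtype)[y]) / N
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        if regularization:
            for layer in self.layers:
                for name in layer.penalized():
                    layer.grads[name] = layer.grads[name] + (
                        regularization * layer.params[name]
                    )
        return loss, acc


def realize_network(plan: LayerPlan, rng=None, bn_decay: float = 0.1,
                    dtype=np.float32) -> Network:
    """Instantiate a plan with He-initialized weights (seeded by ``rng``)."""
    return Network(plan, rng=rng, bn_decay=bn_decay, dtype=dtype)
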