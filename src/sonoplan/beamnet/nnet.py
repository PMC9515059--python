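"""A compact convolutional regressor on plain NumPy.

Three stride-2 3x3 convolutions with ReLU, dual global pooling (mean and max
per channel), and a two-layer fully connected head with a single scalar
output — a few tens of thousands of parameters, sized for CPU training on
desk-scale synthetic cohorts. Adam follows the schedule used by the training
pipeline (beta1 0.9, beta2 0.999, eps 1e-7). Forward/backward are im2col
matrix multiplications in float32; everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _im2col(xp: np.ndarray, k: int, stride: int):
    """(N, C, Hp, Wp) padded input → (N*OH*OW, C*k*k) patch matrix."""
    sw = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow = sw.shape[:4]
    return np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(n * oh * ow, c * k * k), (n, oh, ow)


class Conv2d:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3, stride: int = 2):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.k, self.stride = k, stride
        self.pad = k // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self.xp_shape = xp.shape
        cols, (n, oh, ow) = _im2col(xp, self.k, self.stride)
        self.cols = cols
        y = cols @ self.W.reshape(len(self.W), -1).T + self.b
        return y.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, co, oh, ow = dy.shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, co)
        self.dW = (dyf.T @ self.cols).reshape(self.W.shape)
        self.db = dyf.sum(axis=0)
        dcols = dyf @ self.W.reshape(co, -1)  # (N*OH*OW, C*k*k)
        dcols = dcols.reshape(n, oh, ow, -1, self.k, self.k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(self.xp_shape, dtype=DTYPE)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dcols[..., ki, kj]
        p = self.pad
        return dxp[:, :, p : p + self.x_shape[2], p : p + self.x_shape[3]]


class SmallConvNet:
    """3x [conv 3x3 /2 + ReLU] → mean&max pooling → fc → ReLU → fc(1)."""

    def __init__(self, c_in: int = 7, widths: tuple = (16, 32, 64), head: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.convs = []
        c = c_in
        for w in widths:
            self.convs.append(Conv2d(c, w, rng))
            c = w
        self.fc1_W = rng.normal(0.0, np.sqrt(2.0 / (2 * c)), size=(2 * c, head)).astype(DTYPE)
        self.fc1_b = np.zeros(head, dtype=DTYPE)
        self.fc2_W = rng.normal(0.0, np.sqrt(1.0 / head), size=(head, 1)).astype(DTYPE)
        self.fc2_b = np.zeros(1, dtype=DTYPE)
        self.c_in, self.widths, self.head = c_in, tuple(widths), head
        self._adam_state: dict | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, C, H, W) → predictions (N,). Caches activations when training."""
        self._acts = []
        h = np.asarray(x, dtype=DTYPE)
        for conv in self.convs:
            h = conv.forward(h)
            mask = h > 0
            h = h * mask
            self._acts.append(mask)
        self._pre_pool = h
        g_mean = h.mean(axis=(2, 3))
        g_max = h.max(axis=(2, 3))
        self._argmax_mask = h == g_max[:, :, None, None]
        g = np.concatenate([g_mean, g_max], axis=1)  # (N, 2C)
        self._g = g
        z = g @ self.fc1_W + self.fc1_b
        self._z_mask = z > 0
        z = z * self._z_mask
        self._z = z
        return (z @ self.fc2_W + self.fc2_b)[:, 0].astype(float)

    def backward(self, dout: np.ndarray) -> None:
        """dout: (N,) gradient of the scalar predictions."""
        dout = np.asarray(dout, dtype=DTYPE)[:, None]
        self.d_fc2_W = self._z.T @ dout
        self.d_fc2_b = dout.sum(axis=0)
        dz = (dout @ self.fc2_W.T) * self._z_mask
        self.d_fc1_W = self._g.T @ dz
        self.d_fc1_b = dz.sum(axis=0)
        dg = dz @ self.fc1_W.T
        n, c, hh, ww = self._pre_pool.shape
        d_mean = dg[:, :c]
        d_max = dg[:, c:]
        dh = np.broadcast_to(d_mean[:, :, None, None], (n, c, hh, ww)) / (hh * ww)
        # route max gradient to (all) argmax positions, split on ties
        am = self._argmax_mask
        counts = am.sum(axis=(2, 3), keepdims=True)
        dh = dh + am * (d_max[:, :, None, None] / np.maximum(counts, 1))
        dh = dh.astype(DTYPE)
        for conv, mask in zip(reversed(self.convs), reversed(self._acts)):
            dh = conv.backward(dh * mask)

    def _all_params(self):
        out = []
        for i, conv in enumerate(self.convs):
            out.append((f"conv{i}_W", conv, "W", "dW"))
            out.append((f"conv{i}_b", conv, "b", "db"))
        out.append(("fc1_W", self, "fc1_W", "d_fc1_W"))
        out.append(("fc1_b", self, "fc1_b", "d_fc1_b"))
        out.append(("fc2_W", self, "fc2_W", "d_fc2_W"))
        out.append(("fc2_b", self, "fc2_b", "d_fc2_b"))
        return out

    def adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        if self._adam_state is None:
            self._adam_state = {"t": 0, "m": {}, "v": {}}
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        b1c = DTYPE(1.0 - beta1**t)
        b2c = DTYPE(1.0 - beta2**t)
        for name, obj, attr, dattr in self._all_params():
            g = getattr(obj, dattr)
            m = st["m"].setdefault(name, np.zeros_like(g))
            v = st["v"].setdefault(name, np.zeros_like(g))
            m *= DTYPE(beta1)
            m += DTYPE(1 - beta1) * g
            v *= DTYPE(beta2)
            v += DTYPE(1 - beta2) * g * g
            p = getattr(obj, attr)
            p -= DTYPE(lr) * (m / b1c) / (np.sqrt(v / b2c) + DTYPE(eps))

    def state_dict(self) -> dict:
        out = {"c_in": self.c_in, "widths": np.array(self.widths), "head": self.head}
        for name, obj, attr, _ in self._all_params():
            out[name] = getattr(obj, attr)
        return out

    @staticmethod
    def from_state(state: dict) -> "SmallConvNet":
        net = SmallConvNet(
            int(state["c_in"]), tuple(int(w) for w in state["widths"]), int(state["head"])
        )
        for name, obj, attr, _ in net._all_params():
            getattr(obj, attr)[:] = state[name]
        return net


class BeamScorer:
    """A trained network plus its per-channel normalization and feature config.

    The network regresses on a unit output scale; predictions are mapped to MU
    by ``output_scale`` (default 300, the per-beam MU cap) so that optimizer
    steps traverse the physical weight range within a short epoch budget.
    ``predict`` standardizes inputs with the statistics recorded at training
    time and clamps outputs to the physical MU range [0, 300].
    """

    W_MAX = 300.0

    def __init__(self, net: SmallConvNet, channel_mean: np.ndarray, channel_std: np.ndarray,
                 feature_config: dict | None = None, seed: int | None = None,
                 output_scale: float = 300.0):
        self.net = net
        self.channel_mean = np.asarray(channel_mean, dtype=float).reshape(-1)
        self.channel_std = np.maximum(np.asarray(channel_std, dtype=float).reshape(-1), 1e-6)
        self.feature_config = dict(feature_config or {})
        self.seed = seed
        self.output_scale = float(output_scale)

    def normalize(self, features: np.ndarray) -> np.ndarray:
        f = np.asarray(features, dtype=DTYPE)
        if f.ndim == 3:
            f = f[None]
        mean = self.channel_mean.astype(DTYPE)[:, None, None]
        std = self.channel_std.astype(DTYPE)[:, None, None]
        return (f - mean) / std

    def raw(self, features: np.ndarray) -> np.ndarray:
        return self.net.forward(self.normalize(features)) * self.output_scale

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predicted beam weight(s), clamped to [0, 300] MU."""
        out = self.raw(features)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite scorer output")
        return np.clip(out, 0.0, self.W_MAX)

    def save(self, path_npz, path_json=None) -> None:
        state = self.net.state_dict()
        state["channel_mean"] = self.channel_mean
        state["channel_std"] = self.channel_std
        state["output_scale"] = self.output_scale
        np.savez(path_npz, **state)
        if path_json is not None:
            with open(path_json, "w") as f:
                json.dump(
                    {"backbone": "small-conv", "widths": list(self.net.widths),
                     "head": self.net.head, "feature_config": self.feature_config,
                     "seed": self.seed},
                    f, indent=1,
                )

    @staticmethod
    def load(path_npz, path_json=None) -> "BeamScorer":
        state = dict(np.load(path_npz))
        net = SmallConvNet.from_state(state)
        cfg, seed = {}, None
        if path_json is not None:
            with open(path_json) as f:
                meta = json.load(f)
            cfg, seed = meta.get("feature_config", {}), meta.get("seed")
        return BeamScorer(net, state["channel_mean"], state["channel_std"], cfg, seed,
                          float(state.get("output_scale", 300.0)))
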