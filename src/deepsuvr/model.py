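"""The SUVR correction-factor network.

A small 3D convolutional encoder reads a cerebellum-normalized,
brain-masked PET volume; its flattened features are concatenated with a
length-5 tracer one-hot vector and passed through a fully connected head
ending in a sigmoid scaled by 2, so the correction factor CF is always in
the open interval (0, 2): the model can halve or double an SUVR but never
produce a negative or unbounded correction.

Architecture (encoder): N blocks of [conv3d(kernel=4, stride=4) ->
instance norm -> LeakyReLU].  Head: 2 x [dropout -> linear -> batch norm
-> tanh], then linear -> sigmoid -> x2.  Because stride equals kernel
size, each convolution is an exact linear map on non-overlapping 4x4x4
patches; the whole network is implemented in numpy with hand-derived
backward passes, and gradients are verified against finite differences in
the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantom import TRACERS

__all__ = [
    "NetworkConfig",
    "CorrectionModel",
    "build_network",
    "predict_correction_factor",
    "tracer_one_hot",
    "desk_config",
    "paper_config",
    "Adam",
]

_EPS = 1e-5


def tracer_one_hot(tracer: str | list[str]) -> np.ndarray:
    """Fixed global one-hot encoding in the order (PIB, NAV, FBB, FBP, FMM)."""
    if isinstance(tracer, str):
        tracer = [tracer]
    out = np.zeros((len(tracer), len(TRACERS)))
    for i, t in enumerate(tracer):
        out[i, TRACERS.index(t)] = 1.0
    return out


@dataclass
class NetworkConfig:
    input_shape: tuple[int, int, int]
    conv_channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 4
    stride: int = 4
    fc_hidden: tuple[int, ...] = (128, 64)
    dropout: float = 0.5
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.stride != self.kernel:
            raise ValueError("this encoder requires stride == kernel (patch convolutions)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["tracer_order"] = list(TRACERS)
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkConfig":
        d = json.loads(Path(path).read_text())
        d.pop("tracer_order", None)
        d["input_shape"] = tuple(d["input_shape"])
        d["conv_channels"] = tuple(d["conv_channels"])
        d["fc_hidden"] = tuple(d["fc_hidden"])
        return cls(**d)


def desk_config(input_shape, seed: int = 0) -> NetworkConfig:
    """Down-scaled configuration for CPU-sized grids (two conv blocks).

    Dropout is disabled here: at this parameter count it is not needed as
    a regularizer and its gradient noise drowns the tracer one-hot signal,
    driving the correction factor toward the degenerate collapsed optimum.
    The full-scale preset keeps the 0.5 rate.
    """
    return NetworkConfig(
        input_shape=tuple(input_shape),
        conv_channels=(8, 16),
        fc_hidden=(32, 16),
        dropout=0.0,
        seed=seed,
    )


def paper_config(input_shape=(91, 109, 91), seed: int = 0) -> NetworkConfig:
    """Full-scale preset: four conv blocks, channels 16..128, FC (128, 64)."""
    return NetworkConfig(input_shape=tuple(input_shape), seed=seed)


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _pad_to_multiple(x: np.ndarray, k: int):
    """Zero-pad trailing spatial dims of (N, C, D, H, W) up to multiples of k."""
    pads = [(0, 0), (0, 0)]
    for s in x.shape[2:]:
        pads.append((0, (-s) % k))
    if any(p[1] for p in pads):
        x = np.pad(x, pads)
    return x


class _ConvPatch:
    """3D convolution with stride == kernel: a linear map on 4x4x4 patches."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k**3
        self.k = k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        k = self.k
        self._in_shape = x.shape
        x = _pad_to_multiple(x, k)
        n, c, d, h, w = x.shape
        dd, hh, ww = d // k, h // k, w // k
        patches = (
            x.reshape(n, c, dd, k, hh, k, ww, k)
            .transpose(0, 2, 4, 6, 1, 3, 5, 7)
            .reshape(n, dd * hh * ww, c * k**3)
        )
        y = patches @ self.W.value.T + self.b.value
        self._cache = (patches, (n, c, d, h, w), (dd, hh, ww))
        return y.reshape(n, dd, hh, ww, -1).transpose(0, 4, 1, 2, 3)

    def backward(self, dy):
        patches, (n, c, d, h, w), (dd, hh, ww) = self._cache
        k = self.k
        dy2 = dy.transpose(0, 2, 3, 4, 1).reshape(n, dd * hh * ww, -1)
        self.W.grad += np.einsum("npo,npf->of", dy2, patches)
        self.b.grad += dy2.sum(axis=(0, 1))
        dp = dy2 @ self.W.value
        dx = (
            dp.reshape(n, dd, hh, ww, c, k, k, k)
            .transpose(0, 4, 1, 5, 2, 6, 3, 7)
            .reshape(n, c, d, h, w)
        )
        d0, h0, w0 = self._in_shape[2:]
        return dx[:, :, :d0, :h0, :w0]


class _InstanceNorm:
    """Per-sample, per-channel normalization over the spatial axes (no affine)."""

    def params(self):
        return []

    def forward(self, x):
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + _EPS)
        y = (x - mu) * inv
        self._cache = (y, inv)
        return y

    def backward(self, dy):
        y, inv = self._cache
        ax = (2, 3, 4)
        m = dy.mean(axis=ax, keepdims=True)
        my = (dy * y).mean(axis=ax, keepdims=True)
        return inv * (dy - m - y * my)


class _LeakyReLU:
    def __init__(self, slope: float):
        self.slope = slope

    def params(self):
        return []

    def forward(self, x):
        self._cache = x > 0
        return np.where(self._cache, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._cache, dy, self.slope * dy)


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-lim, lim, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._cache = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._cache
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class _BatchNorm:
    """1-d batch norm with affine parameters and running statistics."""

    def __init__(self, n: int, momentum: float = 0.1):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        if not train:
            return dxhat * inv
        return inv * (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0))


class CorrectionModel:
    """Trained (or trainable) correction-factor network.

    ``forward`` keeps layer caches for ``backward``; inference goes through
    ``predict`` which disables dropout and uses batch-norm running stats.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel
        self.convs = []
        c_in = 1
        for c_out in config.conv_channels:
            self.convs.append(
                (_ConvPatch(c_in, c_out, k, rng), _InstanceNorm(), _LeakyReLU(config.leaky_slope))
            )
            c_in = c_out
        # compute flattened feature length by a dry run on zeros
        dummy = np.zeros((1, 1, *config.input_shape))
        for conv, inorm, act in self.convs:
            dummy = conv.forward(dummy)
        self.feature_len = int(np.prod(dummy.shape[1:]))
        if self.feature_len < 1:
            raise ValueError(f"input shape {config.input_shape} incompatible with the encoder")
        self.fc_input_len = self.feature_len + len(TRACERS)

        self.fcs = []
        n_in = self.fc_input_len
        for n_out in config.fc_hidden:
            self.fcs.append((_Linear(n_in, n_out, rng), _BatchNorm(n_out)))
            n_in = n_out
        self.head = _Linear(n_in, 1, rng)
        self.training = False

    # ---- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Param]:
        out = []
        for conv, inorm, act in self.convs:
            out += conv.params()
        for lin, bn in self.fcs:
            out += lin.params() + bn.params()
        out += self.head.params()
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # ---- forward / backward -------------------------------------------------
    def forward(
        self,
        volumes: np.ndarray,
        one_hot: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """CF in (0, 2) for a batch of volumes (N, D, H, W) or (N, 1, D, H, W)."""
        x = np.asarray(volumes, dtype=np.float64)
        if x.ndim == 4:
            x = x[:, None]
        for conv, inorm, act in self.convs:
            x = act.forward(inorm.forward(conv.forward(x)))
        self._conv_out_shape = x.shape
        feats = x.reshape(x.shape[0], -1)
        h = np.concatenate([feats, np.asarray(one_hot, dtype=np.float64)], axis=1)
        self._drop_masks = []
        for lin, bn in self.fcs:
            if train and self.config.dropout > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                keep = 1.0 - self.config.dropout
                mask = (rng.uniform(size=h.shape) < keep) / keep
            else:
                mask = np.ones_like(h)
            self._drop_masks.append(mask)
            h = np.tanh(bn.forward(lin.forward(h * mask), train))
            bn._tanh_out = h
        z = self.head.forward(h)[:, 0]
        s = 1.0 / (1.0 + np.exp(-z))
        self._sig = s
        return 2.0 * s

    def backward(self, dcf: np.ndarray) -> None:
        """Accumulate parameter gradients of sum(dcf * CF)."""
        s = self._sig
        dz = np.asarray(dcf, dtype=np.float64) * 2.0 * s * (1.0 - s)
        dh = self.head.backward(dz[:, None])
        for (lin, bn), mask in zip(reversed(self.fcs), reversed(self._drop_masks)):
            dh = dh * (1.0 - bn._tanh_out**2)
            dh = bn.backward(dh)
            dh = lin.backward(dh)
            dh = dh * mask
        dfeats = dh[:, : self.feature_len]
        dx = dfeats.reshape(self._conv_out_shape)
        for conv, inorm, act in reversed(self.convs):
            dx = conv.backward(inorm.backward(act.backward(dx)))

    def predict(self, volumes: np.ndarray, one_hot: np.ndarray) -> np.ndarray:
        """Deterministic inference-mode CFs (dropout off, frozen norms)."""
        return self.forward(volumes, one_hot, train=False)

    def get_state(self):
        """Snapshot of all weights and batch-norm running statistics."""
        return (
            [p.value.copy() for p in self.parameters()],
            [(bn.running_mean.copy(), bn.running_var.copy()) for _, bn in self.fcs],
        )

    def set_state(self, state) -> None:
        values, bn_stats = state
        for p, v in zip(self.parameters(), values):
            p.value[...] = v
        for (_, bn), (rm, rv) in zip(self.fcs, bn_stats):
            bn.running_mean[...] = rm
            bn.running_var[...] = rv

    # ---- checkpointing ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        for j, (lin, bn) in enumerate(self.fcs):
            arrays[f"bn{j}_mean"] = bn.running_mean
            arrays[f"bn{j}_var"] = bn.running_var
        np.savez(path, **arrays)
        self.config.to_json(path.with_suffix(".json"))

    @classmethod
    def load(cls, path: str | Path) -> "CorrectionModel":
        path = Path(path)
        config = NetworkConfig.from_json(path.with_suffix(".json"))
        model = cls(config)
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"p{i}"]
        for j, (lin, bn) in enumerate(model.fcs):
            bn.running_mean[...] = data[f"bn{j}_mean"]
            bn.running_var[...] = data[f"bn{j}_var"]
        return model


def build_network(config: NetworkConfig) -> CorrectionModel:
    """Construct a correction model with seed-deterministic initialization."""
    return CorrectionModel(config)


def predict_correction_factor(
    model: CorrectionModel,
    normalized_volume: np.ndarray,
    tracer: str,
    reference_mask: np.ndarray | None = None,
) -> float:
    """CF for a single cerebellum-normalized volume.

    If ``reference_mask`` is supplied, the cerebellum mean of the input is
    checked to be 1 within 1e-3, catching un-normalized volumes.
    """
    vol = np.asarray(normalized_volume, dtype=np.float64)
    if reference_mask is not None:
        ref = np.asarray(reference_mask, dtype=np.float64)
        mean = float((vol * ref).sum() / ref.sum())
        if abs(mean - 1.0) > 1e-3:
            raise ValueError(
                f"input volume is not SUVR-normalized (cerebellum mean {mean:.4f} != 1)"
            )
    cf = model.predict(vol[None], tracer_one_hot(tracer))
    return float(cf[0])


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
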