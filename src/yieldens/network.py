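"""The two-layer CNN-DNN base network for county-level yield prediction.

Architecture
------------
First layer: one small 1-D convolutional branch per input sequence —
five weather branches (one per weather variable, weekly in-season values)
and ten soil branches (one per soil variable, values over ten profile
depths).  Weather branch outputs feed a one-hidden-layer aggregator
(FC_W, 60 units); soil branch outputs feed FC_S (40 units).  The remaining
flat covariates (planting progress, period aggregates, yield trend) pass
through a three-hidden-layer network FC1 (64, 32, 16).

Second layer: the three first-layer outputs are concatenated and a
fully connected head FC2 (128, 64, with dropout 0.5 after each of its two
hidden layers) produces a single linear yield prediction.

Convolutions are valid (no padding), stride 1; downsampling is average
pooling with window 2 and stride 2.  All hidden activations are ReLU; the
output is linear.  Training minimizes mean squared error with Adam.

The whole network — forward pass, backprop, Adam — is implemented in NumPy;
gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import FeatureBlocks


class ShapeError(ValueError):
    """A conv/pool chain annihilates its input sequence."""


class TrainingError(RuntimeError):
    """Loss became non-finite during optimization."""


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters fully determining one base model.

    The default values are the full-scale configuration (4 filters per conv
    layer, 1000 epochs at learning rate 1e-4, batch 16); heterogeneous
    ensemble variants change only ``n_filters`` (2–6).  Use :meth:`reduced`
    for desk-scale experiments.
    """

    n_filters: int = 4
    weather_kernels: tuple[int, ...] = (6, 3, 3)
    soil_kernels: tuple[int, ...] = (3, 3, 3)
    weather_pools: tuple[bool, ...] = (True, True, True)
    soil_pools: tuple[bool, ...] = (True, True, False)
    fc_w: int = 60
    fc_s: int = 40
    fc1: tuple[int, ...] = (64, 32, 16)
    fc2: tuple[int, ...] = (128, 64)
    dropout: float = 0.5
    learning_rate: float = 1e-4
    lr_schedule: str = "constant"  # "constant" | "cosine"
    epochs: int = 1000
    batch_size: int = 16
    pad_fallback: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError("n_filters must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if len(self.weather_kernels) != 3 or len(self.soil_kernels) != 3:
            raise ValueError("kernel sequences are fixed-length 3")
        if min(self.fc_w, self.fc_s, *self.fc1, *self.fc2) < 1:
            raise ValueError("all layer widths must be positive")

    def reduced(self, **overrides) -> "NetworkSpec":
        """Desk-scale variant: few epochs with a training configuration
        adapted to that budget (higher learning rate, smaller batches,
        lighter dropout).  The architecture itself is unchanged."""
        base = dict(
            asdict(self),
            epochs=50,
            learning_rate=2e-3,
            lr_schedule="cosine",
            batch_size=8,
            dropout=0.2,
        )
        base.update(overrides)
        for k in ("weather_kernels", "soil_kernels", "weather_pools", "soil_pools", "fc1", "fc2"):
            base[k] = tuple(base[k])
        return NetworkSpec(**base)


def conv_stack_output_shape(
    input_length: int,
    kernels,
    n_filters: int,
    pool_after,
    pad_fallback: bool = True,
) -> tuple[int, int]:
    """Output (channels, length) of a valid-conv / stride-2-avg-pool chain.

    Valid convolution maps length L to L − k + 1; pooling to floor(L/2).
    If a remaining length is shorter than the next kernel, the sequence is
    left-padded with edge values up to the kernel length when
    ``pad_fallback`` is on — otherwise a :class:`ShapeError` is raised.
    """
    if input_length < 1:
        raise ShapeError("input length must be >= 1")
    L = int(input_length)
    for k, pool in zip(kernels, pool_after):
        if L < k:
            if not pad_fallback:
                raise ShapeError(
                    f"sequence of length {L} cannot take a valid kernel-{k} convolution"
                )
            L = k
        L = L - k + 1
        if pool:
            L = L // 2
        if L < 1:
            raise ShapeError("conv/pool chain annihilated the sequence")
    return (int(n_filters), L)


# ---------------------------------------------------------------------------
# layers (forward caches what backward needs; backward stores param grads)
# ---------------------------------------------------------------------------

class Conv1D:
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init for ReLU chains
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        self._in_shape = x.shape
        return np.einsum("bilk,oik->bol", self._windows, self.W) + self.b[None, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("bilk,bol->oik", self._windows, g)
        self.db = g.sum(axis=(0, 2))
        dx = np.zeros(self._in_shape)
        L_out = g.shape[2]
        for k in range(self.kernel):
            dx[:, :, k : k + L_out] += np.einsum("bol,oi->bil", g, self.W[:, :, k])
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class AvgPool1D:
    """Average pooling, window 2, stride 2; a trailing odd element is dropped."""

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        L_out = x.shape[2] // 2
        self._in_shape, self._L_out = x.shape, L_out
        return 0.5 * (x[:, :, 0 : 2 * L_out : 2] + x[:, :, 1 : 2 * L_out : 2])

    def backward(self, g: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape)
        dx[:, :, 0 : 2 * self._L_out : 2] = 0.5 * g
        dx[:, :, 1 : 2 * self._L_out : 2] = 0.5 * g
        return dx

    def params(self):
        return []


class EdgePadLeft:
    """Left-pad a too-short sequence with its edge value up to ``target``."""

    def __init__(self, target: int):
        self.target = target

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._pad = max(0, self.target - x.shape[2])
        if self._pad == 0:
            return x
        edge = np.repeat(x[:, :, :1], self._pad, axis=2)
        return np.concatenate([edge, x], axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._pad == 0:
            return g
        dx = g[:, :, self._pad :].copy()
        dx[:, :, 0] += g[:, :, : self._pad].sum(axis=2)
        return dx

    def params(self):
        return []


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask

    def params(self):
        return []


class Dropout:
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask

    def params(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


# ---------------------------------------------------------------------------
# the full base network
# ---------------------------------------------------------------------------

def _conv_branch(spec: NetworkSpec, input_length: int, kernels, pools, rng) -> tuple[Sequential, int]:
    layers: list = []
    L, c_in = input_length, 1
    for k, pool in zip(kernels, pools):
        if L < k:
            if not spec.pad_fallback:
                raise ShapeError(
                    f"branch length {L} < kernel {k} and padding fallback disabled"
                )
            layers.append(EdgePadLeft(k))
            L = k
        layers.append(Conv1D(c_in, spec.n_filters, k, rng))
        layers.append(ReLU())
        L, c_in = L - k + 1, spec.n_filters
        if pool:
            layers.append(AvgPool1D())
            L = L // 2
        if L < 1:
            raise ShapeError("conv/pool chain annihilated the sequence")
    return Sequential(layers), spec.n_filters * L


class BaseNetwork:
    """Untrained CNN-DNN model for fixed input dimensions.

    Parameters
    ----------
    spec : NetworkSpec
    weather_length : int
        In-season weeks per weather variable (32 at the default window).
    n_other : int
        Width of the flat covariate vector fed to FC1.
    n_weather_vars, n_soil_vars, soil_depths : int
        Branch counts and soil sequence length.
    """

    def __init__(
        self,
        spec: NetworkSpec,
        weather_length: int,
        n_other: int,
        n_weather_vars: int = 5,
        n_soil_vars: int = 10,
        soil_depths: int = 10,
    ):
        self.spec = spec
        self.weather_length = weather_length
        self.n_other = n_other
        self.n_weather_vars = n_weather_vars
        self.n_soil_vars = n_soil_vars
        self.soil_depths = soil_depths
        rng = np.random.default_rng(spec.seed)

        self.weather_branches, w_width = zip(
            *[
                _conv_branch(spec, weather_length, spec.weather_kernels, spec.weather_pools, rng)
                for _ in range(n_weather_vars)
            ]
        )
        self.soil_branches, s_width = zip(
            *[
                _conv_branch(spec, soil_depths, spec.soil_kernels, spec.soil_pools, rng)
                for _ in range(n_soil_vars)
            ]
        )
        self._w_flat = list(w_width)
        self._s_flat = list(s_width)

        self.fc_w = Sequential([Dense(sum(w_width), spec.fc_w, rng), ReLU()])
        self.fc_s = Sequential([Dense(sum(s_width), spec.fc_s, rng), ReLU()])
        fc1_layers: list = []
        d = n_other
        for width in spec.fc1:
            fc1_layers += [Dense(d, width, rng), ReLU()]
            d = width
        self.fc1 = Sequential(fc1_layers)

        head_layers: list = []
        d = spec.fc_w + spec.fc_s + spec.fc1[-1]
        self.head_input_width = d
        for width in spec.fc2:
            head_layers += [Dense(d, width, rng), ReLU(), Dropout(spec.dropout)]
            d = width
        head_layers.append(Dense(d, 1, rng))
        self.head = Sequential(head_layers)

    # -- plumbing -------------------------------------------------------
    def _components(self):
        yield from self.weather_branches
        yield from self.soil_branches
        yield self.fc_w
        yield self.fc_s
        yield self.fc1
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        out = []
        for comp in self._components():
            for name, layer in comp.params():
                out.append(getattr(layer, name))
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for comp in self._components():
            for name, layer in comp.params():
                out.append(getattr(layer, "d" + name))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def _check(self, blocks: FeatureBlocks) -> None:
        if blocks.weather.shape[1:] != (self.n_weather_vars, self.weather_length):
            raise ValueError(
                f"weather block shape {blocks.weather.shape[1:]} does not match "
                f"({self.n_weather_vars}, {self.weather_length})"
            )
        if blocks.soil.shape[1:] != (self.n_soil_vars, self.soil_depths):
            raise ValueError("soil block shape mismatch")
        if blocks.other.shape[1] != self.n_other:
            raise ValueError(
                f"other block width {blocks.other.shape[1]} != expected {self.n_other}"
            )

    # -- forward / backward ---------------------------------------------
    def forward(self, blocks: FeatureBlocks, train: bool = False, rng=None) -> np.ndarray:
        self._check(blocks)
        n = len(blocks)
        w_outs = [
            br.forward(blocks.weather[:, i : i + 1, :], train, rng).reshape(n, -1)
            for i, br in enumerate(self.weather_branches)
        ]
        s_outs = [
            br.forward(blocks.soil[:, i : i + 1, :], train, rng).reshape(n, -1)
            for i, br in enumerate(self.soil_branches)
        ]
        hw = self.fc_w.forward(np.concatenate(w_outs, axis=1), train, rng)
        hs = self.fc_s.forward(np.concatenate(s_outs, axis=1), train, rng)
        ho = self.fc1.forward(blocks.other, train, rng)
        h = np.concatenate([hw, hs, ho], axis=1)
        return self.head.forward(h, train, rng)[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        g = self.head.backward(dout[:, None])
        spec = self.spec
        gw = self.fc_w.backward(g[:, : spec.fc_w])
        gs = self.fc_s.backward(g[:, spec.fc_w : spec.fc_w + spec.fc_s])
        self.fc1.backward(g[:, spec.fc_w + spec.fc_s :])
        n = gw.shape[0]
        ofs = 0
        for i, br in enumerate(self.weather_branches):
            chunk = gw[:, ofs : ofs + self._w_flat[i]]
            br.backward(chunk.reshape(n, self.spec.n_filters, -1))
            ofs += self._w_flat[i]
        ofs = 0
        for i, br in enumerate(self.soil_branches):
            chunk = gs[:, ofs : ofs + self._s_flat[i]]
            br.backward(chunk.reshape(n, self.spec.n_filters, -1))
            ofs += self._s_flat[i]


def build_base_network(spec: NetworkSpec, weather_length: int, n_other: int, **kwargs) -> BaseNetwork:
    """Instantiate an untrained base network for the given input widths."""
    return BaseNetwork(spec, weather_length, n_other, **kwargs)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedBase:
    """A fitted base model with a deterministic predict contract."""

    spec: NetworkSpec
    model: BaseNetwork
    y_mean: float
    y_sd: float
    epoch_losses: list[float] = field(default_factory=list)
    data_fingerprint: str = ""

    def predict(self, blocks: FeatureBlocks) -> np.ndarray:
        raw = self.model.forward(blocks, train=False)
        return raw * self.y_sd + self.y_mean


def _fingerprint(blocks: FeatureBlocks) -> str:
    h = hashlib.sha256()
    for a in (blocks.weather, blocks.soil, blocks.other, blocks.y):
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def train_network(
    model: BaseNetwork,
    blocks: FeatureBlocks,
    spec: NetworkSpec,
    seed: int | None = None,
) -> TrainedBase:
    """Fit *model* on *blocks* by Adam on mean squared error.

    Targets are standardized internally (training mean/sd) so the optimizer
    step size is independent of the yield unit; predictions are returned on
    the original scale.  Batches of ``spec.batch_size`` are reshuffled every
    epoch with the run seed; dropout is active only here.
    """
    if not np.all(np.isfinite(blocks.y)):
        raise ValueError("targets must be finite")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    y = blocks.y
    y_mean = float(np.mean(y))
    y_sd = float(np.std(y))
    if y_sd < 1e-12:
        y_sd = 1.0
    y_std = (y - y_mean) / y_sd

    opt = Adam(model.parameters(), lr=spec.learning_rate)
    n = len(blocks)
    losses = []
    for epoch in range(spec.epochs):
        if spec.lr_schedule == "cosine":
            # anneal to ~0 so the final parameters settle instead of hovering
            # in the optimizer's stationary noise ball
            opt.lr = spec.learning_rate * 0.5 * (1.0 + np.cos(np.pi * epoch / spec.epochs))
        elif spec.lr_schedule != "constant":
            raise ValueError(f"unknown lr_schedule {spec.lr_schedule!r}")
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            batch = blocks.take(idx)
            pred = model.forward(batch, train=True, rng=rng)
            resid = pred - y_std[idx]
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}"
                )
            model.backward(2.0 * resid / len(idx))
            opt.step(model.gradients())
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    return TrainedBase(
        spec, model, y_mean, y_sd, losses, data_fingerprint=_fingerprint(blocks)
    )


def predict_yields(base: TrainedBase, blocks: FeatureBlocks) -> np.ndarray:
    """One deterministic finite prediction per record (dropout disabled)."""
    pred = base.predict(blocks)
    if not np.all(np.isfinite(pred)):
        raise TrainingError("model produced non-finite predictions")
    return pred
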