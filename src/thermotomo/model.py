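"""Convolutional autoencoder for thermal-volume reconstruction.

The network maps an unfiltered-backprojection volume to a refined
temperature distribution.  Axial slices are treated as the channels of a
2D convolutional network: a 100×100×50 volume becomes a 50-channel
128×128 image after zero padding.  The encoder stacks blocks of
3×3 convolution → batch normalization → leaky ReLU → 2×2 max pooling
(32, 64, 128, 256 filters; an optional fifth block with 512 filters
shrinks the bottleneck from 8×8×256 to 4×4×512); the decoder mirrors it
with stride-2 transposed convolutions, and a final linear 3×3
convolution maps back to 50 output channels, cropped to 100×100.

Everything — convolutions, batch normalization, pooling, Adam, the MSE
training loop — is implemented on numpy arrays (float32), so training
and inference are fully deterministic under a seed and run on any CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .heatsim import ContractError, TemperatureVolume


class ConstructionError(ValueError):
    """The architecture configuration produces inconsistent shapes."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shape and filter schedule of the autoencoder.

    ``input_hw`` must be divisible by 2**n_blocks; the bottleneck is
    ``input_hw / 2**n_blocks`` square with ``filters[-1]`` channels
    (8×8×256 for the default four blocks at 128×128, 4×4×512 with five).
    """

    n_blocks: int = 4
    filters: tuple[int, ...] = (32, 64, 128, 256)
    in_channels: int = 50
    out_channels: int = 50
    input_hw: int = 128
    output_hw: int = 100
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.n_blocks not in (4, 5):
            raise ConstructionError("n_blocks must be 4 or 5")
        filters = tuple(self.filters)
        if len(filters) != self.n_blocks:
            if self.n_blocks == 5 and len(filters) == 4:
                filters = filters + (filters[-1] * 2,)
            else:
                raise ConstructionError(
                    f"{self.n_blocks} blocks need {self.n_blocks} filter counts")
        object.__setattr__(self, "filters", filters)
        if self.input_hw % (2 ** self.n_blocks) != 0:
            raise ConstructionError(
                f"input size {self.input_hw} is not divisible by 2^{self.n_blocks}")
        if self.output_hw > self.input_hw:
            raise ConstructionError("output size cannot exceed the padded input")

    @property
    def bottleneck_hw(self) -> int:
        return self.input_hw // (2 ** self.n_blocks)


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 32
    max_epochs: int = 500
    learning_rate: float = 1e-3
    patience: int = 25
    n_rotations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConstructionError("batch size and epochs must be >= 1")


# ---------------------------------------------------------------------------
# Layer primitives (NCHW, float32)
# ---------------------------------------------------------------------------

def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Stride-1, pad-1 3×3 convolution: (N,C,H,W) × (F,C,3,3) → (N,F,H,W)."""
    n, c, h, ww = x.shape
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, f, h * ww), dtype=x.dtype)
    for ki in range(3):
        for kj in range(3):
            xs = np.ascontiguousarray(xp[:, :, ki:ki + h, kj:kj + ww]
                                      ).reshape(n, c, h * ww)
            out += np.matmul(w[:, :, ki, kj], xs)
    out = out.reshape(n, f, h, ww)
    if b is not None:
        out += b[None, :, None, None]
    return out


def _conv3x3_input_grad(dout: np.ndarray, w: np.ndarray,
                        in_shape: tuple) -> np.ndarray:
    n, c, h, ww = in_shape
    f = w.shape[0]
    dxp = np.zeros((n, c, h + 2, ww + 2), dtype=dout.dtype)
    dflat = dout.reshape(n, f, h * ww)
    for ki in range(3):
        for kj in range(3):
            tmp = np.matmul(w[:, :, ki, kj].T, dflat).reshape(n, c, h, ww)
            dxp[:, :, ki:ki + h, kj:kj + ww] += tmp
    return dxp[:, :, 1:-1, 1:-1]


def _conv3x3_weight_grad(x: np.ndarray, dout: np.ndarray) -> np.ndarray:
    n, c, h, ww = x.shape
    f = dout.shape[1]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dflat = dout.reshape(n, f, h * ww)
    dw = np.zeros((f, c, 3, 3), dtype=x.dtype)
    for ki in range(3):
        for kj in range(3):
            xs = np.ascontiguousarray(xp[:, :, ki:ki + h, kj:kj + ww]
                                      ).reshape(n, c, h * ww)
            dw[:, :, ki, kj] = np.matmul(dflat, xs.transpose(0, 2, 1)).sum(axis=0)
    return dw


class _Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []


class Conv2d(_Layer):
    def __init__(self, c_in, c_out, rng, name=""):
        super().__init__()
        scale = math.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params, self.grads = [self.w, self.b], [self.dw, self.db]
        self.name = name

    def forward(self, x, train):
        self.x = x
        return _conv3x3(x, self.w, self.b)

    def backward(self, dout):
        self.dw[...] = _conv3x3_weight_grad(self.x, dout)
        self.db[...] = dout.sum(axis=(0, 2, 3))
        return _conv3x3_input_grad(dout, self.w, self.x.shape)


class ConvTranspose2d(_Layer):
    """3×3 transposed convolution with stride 2 (output = 2× input size)."""

    def __init__(self, c_in, c_out, rng, name=""):
        super().__init__()
        scale = math.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params, self.grads = [self.w, self.b], [self.dw, self.db]
        self.name = name

    def _stuff(self, x):
        n, c, h, ww = x.shape
        y = np.zeros((n, c, 2 * h, 2 * ww), dtype=x.dtype)
        y[:, :, ::2, ::2] = x
        return y

    def forward(self, x, train):
        self.x_shape = x.shape
        self.stuffed = self._stuff(x)
        return _conv3x3(self.stuffed, self.w, self.b)

    def backward(self, dout):
        self.dw[...] = _conv3x3_weight_grad(self.stuffed, dout)
        self.db[...] = dout.sum(axis=(0, 2, 3))
        dstuff = _conv3x3_input_grad(dout, self.w, self.stuffed.shape)
        return dstuff[:, :, ::2, ::2]


class BatchNorm2d(_Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params, self.grads = [self.gamma, self.beta], [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean[None, :, None, None]) * self.inv_std[None, :, None, None]
        return self.gamma[None, :, None, None] * self.xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        n, c, h, w = dout.shape
        m = n * h * w
        self.dgamma[...] = (dout * self.xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self.xhat * (dxhat * self.xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * self.inv_std[None, :, None, None]


class LeakyReLU(_Layer):
    def __init__(self, slope=0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, train):
        self.mask = x >= 0
        return np.where(self.mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self.mask, dout, self.slope * dout)


class MaxPool2x2(_Layer):
    def forward(self, x, train):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ConstructionError(f"odd spatial size {h}x{w} before pooling")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self.win_shape = win.shape
        flat = win.reshape(n, c, h // 2, w // 2, 4)
        self.idx = flat.argmax(axis=-1)
        self.in_shape = x.shape
        return np.take_along_axis(flat, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self.in_shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(flat, self.idx[..., None], dout[..., None], axis=-1)
        win = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return win.reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# Padding / cropping between the 100×100 grid and the 128×128 network
# ---------------------------------------------------------------------------

def pad_input(volume: np.ndarray | TemperatureVolume, target_hw: int = 128
              ) -> np.ndarray:
    """Zero-pad a (H, W, C) volume symmetrically in-plane to ``target_hw``.

    A 100×100×50 volume gains 14 zero voxels per side; ``crop_output``
    inverts the padding exactly.  Returns a (C, target_hw, target_hw)
    float32 tensor (slices as channels).
    """
    values = volume.values if isinstance(volume, TemperatureVolume) else volume
    h, w, c = values.shape
    if h > target_hw or w > target_hw:
        raise ContractError(f"volume {h}x{w} exceeds the padded size {target_hw}")
    if (target_hw - h) % 2 or (target_hw - w) % 2:
        raise ContractError("padding must be symmetric (even size difference)")
    ph, pw = (target_hw - h) // 2, (target_hw - w) // 2
    padded = np.pad(values, ((ph, ph), (pw, pw), (0, 0))).astype(np.float32)
    return np.ascontiguousarray(np.moveaxis(padded, 2, 0))


def crop_output(tensor: np.ndarray, output_hw: int) -> np.ndarray:
    """Central crop of a (C, H, W) tensor back to (output_hw², C) layout."""
    c, h, w = tensor.shape
    ph, pw = (h - output_hw) // 2, (w - output_hw) // 2
    cropped = tensor[:, ph:ph + output_hw, pw:pw + output_hw]
    return np.moveaxis(cropped, 0, 2)


# ---------------------------------------------------------------------------
# The autoencoder
# ---------------------------------------------------------------------------

class ConvAutoencoder:
    """Encoder/decoder reconstruction network (see module docstring)."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        s = config.negative_slope
        self.layers: list[_Layer] = []
        c_prev = config.in_channels
        for bi, f in enumerate(config.filters):
            self.layers += [Conv2d(c_prev, f, rng, name=f"enc{bi + 1}"),
                            BatchNorm2d(f), LeakyReLU(s), MaxPool2x2()]
            c_prev = f
        for bi, f in enumerate(reversed(config.filters)):
            self.layers += [ConvTranspose2d(c_prev, f, rng, name=f"dec{bi + 1}"),
                            BatchNorm2d(f), LeakyReLU(s)]
            c_prev = f
        self.layers.append(Conv2d(c_prev, config.out_channels, rng, name="head"))
        self._check_shapes()

    def _check_shapes(self) -> None:
        hw = self.config.input_hw
        for bi in range(self.config.n_blocks):
            if hw % 2:
                raise ConstructionError(f"encoder block {bi + 1}: odd size {hw}")
            hw //= 2
        if hw != self.config.bottleneck_hw:
            raise ConstructionError("bottleneck size mismatch")

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C_in, H, W) → (N, C_out, H, W)."""
        expected = (self.config.in_channels, self.config.input_hw,
                    self.config.input_hw)
        if x.shape[1:] != expected:
            raise ContractError(f"expected input {expected}, got {x.shape[1:]}")
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def bottleneck_shape(self) -> tuple[int, int, int]:
        hw = self.config.bottleneck_hw
        return (hw, hw, self.config.filters[-1])

    # -- parameter access ---------------------------------------------------

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def state_arrays(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                state[f"layer{i}_p{j}"] = p
            if isinstance(layer, BatchNorm2d):
                state[f"layer{i}_rm"] = layer.running_mean
                state[f"layer{i}_rv"] = layer.running_var
        return state

    def load_state(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = state[f"layer{i}_p{j}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"layer{i}_rm"]
                layer.running_var[...] = state[f"layer{i}_rv"]

    def save(self, path) -> None:
        import yaml
        from dataclasses import asdict

        np.savez(path, **self.state_arrays())
        with open(str(path) + ".arch.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh)

    @classmethod
    def load(cls, path) -> "ConvAutoencoder":
        import yaml

        with open(str(path) + ".arch.yaml") as fh:
            raw = yaml.safe_load(fh)
        raw["filters"] = tuple(raw["filters"])
        model = cls(ArchitectureConfig(**raw))
        with np.load(path) as data:
            model.load_state({k: data[k] for k in data.files})
        return model


def build_autoencoder(config: ArchitectureConfig | None = None, seed: int = 0
                      ) -> ConvAutoencoder:
    """Construct the reconstruction model with seeded He initialization."""
    return ConvAutoencoder(config or ArchitectureConfig(), seed=seed)


# ---------------------------------------------------------------------------
# Adam + training loop
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _tensorize(samples, input_hw):
    xs = np.stack([pad_input(s.input, input_hw) for s in samples])
    ys = np.stack([np.moveaxis(s.target.values.astype(np.float32), 2, 0)
                   for s in samples])
    return xs, ys


def _mse_and_grad(model, pred_full, target):
    """MSE over the central crop; gradient zero outside the crop."""
    hw, out_hw = model.config.input_hw, model.config.output_hw
    p = (hw - out_hw) // 2
    sl = (slice(None), slice(None), slice(p, p + out_hw), slice(p, p + out_hw))
    diff = pred_full[sl] - target
    loss = float(np.mean(diff ** 2))
    grad = np.zeros_like(pred_full)
    grad[sl] = (2.0 / diff.size) * diff
    return loss, grad


def train(
    model: ConvAutoencoder,
    train_samples,
    val_samples,
    config: TrainingConfig | None = None,
    augment: bool = True,
):
    """Train with Adam on voxelwise MSE; returns (model, history DataFrame).

    Each epoch applies the ×``n_rotations`` random axial-rotation
    augmentation to the training set (epoch-stepped seed), shuffles,
    and steps in mini-batches.  The best-validation-loss parameters are
    checkpointed and restored at the end; training stops at
    ``max_epochs`` or after ``patience`` epochs without improvement.
    """
    import pandas as pd

    from .dataset import augment_epoch

    config = config or TrainingConfig()
    opt = Adam(model.parameters(), lr=config.learning_rate)
    val_x, val_y = _tensorize(val_samples, model.config.input_hw) \
        if len(val_samples) else (None, None)
    best_val, best_state, since_best = math.inf, None, 0
    history = []
    shuffle_rng = np.random.default_rng(config.seed + 10_000)
    if not augment:
        xs, ys = _tensorize(list(train_samples), model.config.input_hw)
    for epoch in range(config.max_epochs):
        if augment:
            aug_rng = np.random.default_rng(config.seed + epoch)
            epoch_samples = list(augment_epoch(train_samples, aug_rng,
                                               n_rotations=config.n_rotations))
            xs, ys = _tensorize(epoch_samples, model.config.input_hw)
        order = shuffle_rng.permutation(len(xs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = model.forward(xs[idx], train=True)
            loss, grad = _mse_and_grad(model, pred, ys[idx])
            if not math.isfinite(loss):
                raise TrainingError(f"loss diverged at epoch {epoch}")
            model.backward(grad)
            opt.step(model.gradients())
            losses.append(loss)
        train_loss = float(np.mean(losses))
        if val_x is not None:
            val_loss = _eval_loss(model, val_x, val_y, config.batch_size)
        else:
            val_loss = train_loss
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val, since_best = val_loss, 0
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state(best_state)
    return model, pd.DataFrame(history)


def _eval_loss(model, xs, ys, batch_size) -> float:
    total, count = 0.0, 0
    hw, out_hw = model.config.input_hw, model.config.output_hw
    p = (hw - out_hw) // 2
    for start in range(0, len(xs), batch_size):
        pred = model.forward(xs[start:start + batch_size], train=False)
        diff = pred[:, :, p:p + out_hw, p:p + out_hw] - ys[start:start + batch_size]
        total += float((diff ** 2).sum())
        count += diff.size
    return total / count


def reconstruct(model: ConvAutoencoder, volume: TemperatureVolume
                ) -> TemperatureVolume:
    """Apply the trained model to a backprojection volume.

    Deterministic inference (batch-norm running statistics); the output
    carries the input's grid and support mask, with out-of-support
    voxels zeroed.
    """
    x = pad_input(volume, model.config.input_hw)[None]
    pred = model.forward(x, train=False)[0]
    out = crop_output(pred, model.config.output_hw).astype(np.float64)
    if out.shape != volume.values.shape:
        raise ContractError("model output does not match the volume grid")
    out = out.copy()
    out[~volume.support] = 0.0
    return volume.copy_with(values=out)
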