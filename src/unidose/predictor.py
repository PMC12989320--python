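"""Dose-regression network.

A compact, fixed-configuration 3D convolutional encoder-decoder (U-Net style:
two 3x3x3 convolutions per resolution level, average-pool downsampling,
nearest-neighbour upsampling with skip concatenation, linear 1x1x1 output
head) maps the three-channel input stack to a normalized dose volume. It is
trained with the Huber loss (delta = 1 by default), which behaves like mean
squared error for small residuals and mean absolute error for large ones.

The network predicts dose normalized by the case's maximum prescription
(dp_max), mirroring the prescription-channel normalization; Gy output is
obtained by multiplying back. Forward, backward and the Adam optimizer are
implemented directly in numpy, so training is deterministic given the seed.
Default sizes are desk-scale; they are configurable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelStack
from .grid import VolumeGrid

__all__ = [
    "PredictorConfig",
    "TrainedModel",
    "huber_loss",
    "huber_grad",
    "DoseUNet",
    "train",
    "predict",
]


def huber_loss(pred: np.ndarray, target: np.ndarray, delta: float = 1.0) -> float:
    """Mean per-voxel Huber loss: 0.5 r^2 for |r| <= delta, else
    delta |r| - 0.5 delta^2."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if not delta > 0:
        raise ValueError("delta must be positive")
    r = np.abs(np.asarray(pred, dtype=np.float64) - target)
    quad = 0.5 * r**2
    lin = delta * r - 0.5 * delta**2
    return float(np.mean(np.where(r <= delta, quad, lin)))


def huber_grad(pred: np.ndarray, target: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Gradient of the mean Huber loss w.r.t. pred (clipped residual / n)."""
    r = pred - target
    return np.clip(r, -delta, delta) / r.size


@dataclass
class PredictorConfig:
    depth: int = 3  # resolution levels
    base_width: int = 16  # channels at the first level
    delta: float = 1.0  # Huber threshold
    epochs: int = 100
    batch_size: int = 1  # full-volume samples
    learning_rate: float = 1e-3
    seed: int = 0
    augment_mirror: bool = True

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


# ---------------------------------------------------------------------------
# layers (channels-last, single volume per step)

_OFFSETS = [(dx, dy, dz) for dx in range(3) for dy in range(3) for dz in range(3)]


class _Conv3x3:
    """3x3x3 same-padding convolution, implemented as 27 shifted matmuls."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (27 * cin))
        self.W = rng.normal(0.0, std, size=(27, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self._x_pad = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
        self._x_pad = xp
        d, h, w, _ = x.shape
        y = np.tile(self.b, (d, h, w, 1)).astype(np.float32)
        for o, (dx, dy, dz) in enumerate(_OFFSETS):
            y += xp[dx : dx + d, dy : dy + h, dz : dz + w] @ self.W[o]
        return y

    def backward(self, gy: np.ndarray):
        xp = self._x_pad
        d, h, w, _ = gy.shape
        gW = np.empty_like(self.W)
        gxp = np.zeros_like(xp)
        gy64 = gy
        for o, (dx, dy, dz) in enumerate(_OFFSETS):
            xs = xp[dx : dx + d, dy : dy + h, dz : dz + w]
            gW[o] = np.einsum("xyzc,xyzo->co", xs, gy64)
            gxp[dx : dx + d, dy : dy + h, dz : dz + w] += gy64 @ self.W[o].T
        gb = gy.sum(axis=(0, 1, 2))
        gx = gxp[1:-1, 1:-1, 1:-1]
        return gx, [gW, gb]


class _Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, std, size=(cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gy: np.ndarray):
        gW = np.einsum("xyzc,xyzo->co", self._x, gy)
        gb = gy.sum(axis=(0, 1, 2))
        return gy @ self.W.T, [gW, gb]


def _relu(x):
    return np.maximum(x, 0.0)


def _avgpool2(x):
    d, h, w, c = x.shape
    return x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).mean(axis=(1, 3, 5))


def _avgpool2_back(gy):
    d, h, w, c = gy.shape
    g = np.broadcast_to(
        gy[:, None, :, None, :, None, :] / 8.0, (d, 2, h, 2, w, 2, c)
    )
    return g.reshape(d * 2, h * 2, w * 2, c)


def _upsample2(x):
    return x.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_back(gy):
    d, h, w, c = gy.shape
    return gy.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(1, 3, 5))


class DoseUNet:
    """Fixed compact 3D U-Net regressor (channels-last numpy implementation)."""

    def __init__(self, cfg: PredictorConfig, in_channels: int = 3):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        widths = [cfg.base_width * 2**l for l in range(cfg.depth)]
        self.widths = widths
        self.enc: list[list[_Conv3x3]] = []
        cin = in_channels
        for wl in widths:
            self.enc.append([_Conv3x3(cin, wl, rng), _Conv3x3(wl, wl, rng)])
            cin = wl
        self.dec: list[list[_Conv3x3]] = []
        for l in range(cfg.depth - 2, -1, -1):
            self.dec.append(
                [
                    _Conv3x3(widths[l + 1] + widths[l], widths[l], rng),
                    _Conv3x3(widths[l], widths[l], rng),
                ]
            )
        self.head = _Conv1x1(widths[0], 1, rng)
        self._cache: dict = {}

    # -- parameter plumbing -------------------------------------------------
    def layers(self):
        out = []
        for blk in self.enc + self.dec:
            out.extend(blk)
        out.append(self.head)
        return out

    def get_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params]

    def set_params(self, params: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers():
            layer.W = params[i].copy()
            layer.b = params[i + 1].copy()
            i += 2

    def zero_head(self) -> None:
        self.head.W[:] = 0.0
        self.head.b[:] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("input must be (nx, ny, nz, channels)")
        factor = 2 ** (self.cfg.depth - 1)
        if any(s % factor for s in x.shape[:3]):
            raise ValueError(
                f"volume shape {x.shape[:3]} must be divisible by {factor}"
            )
        x = x.astype(np.float32)
        skips, masks = [], []
        h = x
        for l, blk in enumerate(self.enc):
            if l > 0:
                h = _avgpool2(h)
            pre = []
            for conv in blk:
                z = conv.forward(h)
                pre.append(z > 0)
                h = _relu(z)
            masks.append(pre)
            skips.append(h)
        dmasks, cat_splits = [], []
        for i, blk in enumerate(self.dec):
            l = self.cfg.depth - 2 - i
            h = _upsample2(h)
            cat_splits.append(h.shape[-1])
            h = np.concatenate([h, skips[l]], axis=-1)
            pre = []
            for conv in blk:
                z = conv.forward(h)
                pre.append(z > 0)
                h = _relu(z)
            dmasks.append(pre)
        y = self.head.forward(h)
        self._cache = {"masks": masks, "dmasks": dmasks, "splits": cat_splits}
        return y

    def backward(self, gy: np.ndarray) -> list[np.ndarray]:
        c = self._cache
        grads_map: dict[int, list[np.ndarray]] = {}
        g, pg = self.head.backward(gy.astype(np.float32))
        grads_map[id(self.head)] = pg
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(len(self.dec) - 1, -1, -1):
            l = self.cfg.depth - 2 - i
            blk = self.dec[i]
            for j in (1, 0):
                g = g * c["dmasks"][i][j]
                g, pg = blk[j].backward(g)
                grads_map[id(blk[j])] = pg
            n_up = c["splits"][i]
            g_up, g_skip = g[..., :n_up], g[..., n_up:]
            skip_grads[l] = g_skip
            g = _upsample2_back(g_up)
        for l in range(self.cfg.depth - 1, -1, -1):
            blk = self.enc[l]
            if l in skip_grads:
                g = g + skip_grads[l]
            if l == self.cfg.depth - 1:
                pass
            for j in (1, 0):
                g = g * c["masks"][l][j]
                g, pg = blk[j].backward(g)
                grads_map[id(blk[j])] = pg
            if l > 0:
                g = _avgpool2_back(g)
        out = []
        for layer in self.layers():
            out.extend(grads_map[id(layer)])
        return out


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    """A trained regressor: architecture config + best-validation weights."""

    config: PredictorConfig
    params: list[np.ndarray]
    in_channels: int = 3
    history: dict = field(default_factory=dict)
    best_epoch: int = -1
    manifest_hash: str = ""
    status: str = "ok"

    def network(self) -> DoseUNet:
        net = DoseUNet(self.config, self.in_channels)
        net.set_params(self.params)
        return net

    def save(self, path) -> None:
        np.savez(
            path,
            *self.params,
            _meta=np.array(
                [self.config.depth, self.config.base_width, self.in_channels]
            ),
        )

    @classmethod
    def load(cls, path, config: PredictorConfig | None = None) -> "TrainedModel":
        data = np.load(path)
        meta = data["_meta"]
        cfg = config or PredictorConfig(depth=int(meta[0]), base_width=int(meta[1]))
        params = [data[k] for k in data.files if k != "_meta"]
        return cls(config=cfg, params=params, in_channels=int(meta[2]))


def sample_from_stack(stack: ChannelStack, label: VolumeGrid) -> tuple[np.ndarray, np.ndarray]:
    """(input, target) pair: channel-last stack and label dose / dp_max."""
    x = stack.as_array().astype(np.float32)
    y = (label.values / stack.dp_max_gy)[..., None].astype(np.float32)
    return x, y


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _eval_loss(net: DoseUNet, samples, delta: float) -> float:
    return float(
        np.mean([huber_loss(net.forward(x)[..., 0], y[..., 0], delta) for x, y in samples])
    )


def train(
    train_samples: list[tuple[np.ndarray, np.ndarray]],
    cfg: PredictorConfig | None = None,
    val_samples: list[tuple[np.ndarray, np.ndarray]] | None = None,
    manifest_hash: str = "",
) -> TrainedModel:
    """Train the regressor; checkpoint selection is by best validation loss.

    ``train_samples`` are (input stack, normalized label) pairs from
    :func:`sample_from_stack`. With no validation set, the best training-loss
    epoch is selected. A non-finite loss aborts with the last good checkpoint.
    """
    cfg = cfg or PredictorConfig()
    if len(train_samples) < 2:
        raise ValueError("need at least 2 training cases")
    rng = np.random.default_rng(cfg.seed + 1)
    net = DoseUNet(cfg, in_channels=train_samples[0][0].shape[-1])
    opt = _Adam(net.get_params(), cfg.learning_rate)
    best = (np.inf, -1, [p.copy() for p in net.get_params()])
    hist = {"epoch": [], "train_loss": [], "val_loss": []}
    status = "ok"
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_samples))
        losses = []
        abort = False
        for i in order:
            x, y = train_samples[i]
            if cfg.augment_mirror:
                for ax in (0, 1):
                    if rng.uniform() < 0.5:
                        x = np.flip(x, axis=ax)
                        y = np.flip(y, axis=ax)
            pred = net.forward(np.ascontiguousarray(x))
            y = np.ascontiguousarray(y)
            loss = huber_loss(pred[..., 0], y[..., 0], cfg.delta)
            if not np.isfinite(loss):
                abort = True
                break
            losses.append(loss)
            g = huber_grad(pred, y, cfg.delta)
            grads = net.backward(g)
            params = net.get_params()
            opt.step(params, grads)
            net.set_params(params)
        if abort:
            status = "aborted: non-finite loss; last good checkpoint kept"
            break
        train_loss = float(np.mean(losses))
        val_loss = (
            _eval_loss(net, val_samples, cfg.delta) if val_samples else train_loss
        )
        hist["epoch"].append(epoch)
        hist["train_loss"].append(train_loss)
        hist["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, epoch, [p.copy() for p in net.get_params()])
    return TrainedModel(
        config=cfg,
        params=best[2],
        in_channels=train_samples[0][0].shape[-1],
        history=hist,
        best_epoch=best[1],
        manifest_hash=manifest_hash,
        status=status,
    )


def predict(model: TrainedModel, stack: ChannelStack) -> tuple[VolumeGrid, VolumeGrid]:
    """Predict dose for a channel stack.

    Returns (normalized dose, dose in Gy = normalized * dp_max); negative
    network outputs are clipped to zero.
    """
    net = model.network()
    x = stack.as_array().astype(np.float32)
    out = net.forward(x)[..., 0]
    out = np.maximum(out.astype(np.float64), 0.0)
    norm = stack.prescription.like(out)
    gy = stack.prescription.like(out * stack.dp_max_gy)
    return norm, gy
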