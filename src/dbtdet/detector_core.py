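"""Single-phase fully convolutional detector over 96x96-pixel grid cells.

A compact dense-block CNN implemented directly on numpy with hand-written
forward/backward passes, so the whole pipeline runs on CPU without a deep
learning framework.  The backbone downsamples by a fixed total stride of 96
(pool factors 2,2,2,2,2,3); the head emits 5 channels per cell: a sigmoid
confidence and 4 box-regression values (tanh/2-bounded offsets, free log
scales relative to a 256x256 anchor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .ground_truth import ANCHOR, CELL
from .io_formats import PredictedBox

__all__ = ["DetectorConfig", "DetectionGrid", "Detector", "build_detector",
           "decode_predictions", "save_checkpoint", "load_checkpoint"]

POOL_FACTORS = (2, 2, 2, 2, 2, 3)  # product == CELL == 96
CONFIDENCE_PRIOR = 0.01


@dataclass(frozen=True)
class DetectorConfig:
    """Backbone size knobs; total stride and head width are fixed."""

    growth_rate: int = 8
    blocks: tuple[int, ...] = (2, 2, 2, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if not (1 <= len(self.blocks) <= len(POOL_FACTORS) - 1):
            raise ValueError(
                f"need 1..{len(POOL_FACTORS) - 1} dense blocks to fit the "
                f"stride-{CELL} pooling schedule, got {len(self.blocks)}"
            )
        if any(b < 1 for b in self.blocks):
            raise ValueError("every dense block needs >= 1 layer")


@dataclass
class DetectionGrid:
    """Per-slice model output: confidence in (0,1) plus 4 regression channels."""

    confidence: np.ndarray   # (rows/96, cols/96)
    regression: np.ndarray   # (4, rows/96, cols/96)


# ---------------------------------------------------------------------------
# Layers


class Conv2d:
    """Stride-1 convolution with 'same' padding, via shifted tensordots."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 weight_std: float | None = None):
        fan_in = cin * k * k
        std = weight_std if weight_std is not None else np.sqrt(2.0 / fan_in)
        self.w = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k = k
        self._x_padded: np.ndarray | None = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, _, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.empty((n, h, w, self.w.shape[0]), dtype=np.float32)
        out[:] = self.b
        for di in range(k):
            for dj in range(k):
                view = xp[:, :, di:di + h, dj:dj + w]
                out += np.tensordot(view, self.w[:, :, di, dj], axes=([1], [1]))
        if train:
            self._x_padded = xp
        return np.ascontiguousarray(np.moveaxis(out, 3, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = self._x_padded
        n, _, h, w = dy.shape
        self.gb += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                view = xp[:, :, di:di + h, dj:dj + w]
                self.gw[:, :, di, dj] += np.tensordot(dy, view, axes=([0, 2, 3], [0, 2, 3]))
                grad = np.tensordot(dy, self.w[:, :, di, dj], axes=([1], [0]))
                dxp[:, :, di:di + h, dj:dj + w] += np.moveaxis(grad, 3, 1)
        self._x_padded = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class AvgPool:
    def __init__(self, factor: int):
        self.f = factor

    def params(self):
        return []

    def forward(self, x, train):
        f = self.f
        n, c, h, w = x.shape
        if h % f or w % f:
            raise ValueError(f"input {h}x{w} not divisible by pool factor {f}")
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, dy):
        f = self.f
        return np.repeat(np.repeat(dy, f, axis=2), f, axis=3) / (f * f)


class DenseBlock:
    """Each layer appends ``growth`` channels: x <- concat(x, relu(conv3(x)))."""

    def __init__(self, cin: int, n_layers: int, growth: int, rng):
        self.convs = []
        self.relus = []
        c = cin
        for _ in range(n_layers):
            self.convs.append(Conv2d(c, growth, 3, rng))
            self.relus.append(ReLU())
            c += growth
        self.cout = c

    def params(self):
        out = []
        for conv in self.convs:
            out.extend(conv.params())
        return out

    def forward(self, x, train):
        for conv, relu in zip(self.convs, self.relus):
            y = relu.forward(conv.forward(x, train), train)
            x = np.concatenate([x, y], axis=1)
        return x

    def backward(self, dy):
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            g = conv.w.shape[0]
            dx, dnew = dy[:, :-g], dy[:, -g:]
            dy = dx + conv.backward(relu.backward(np.ascontiguousarray(dnew)))
        return dy


# ---------------------------------------------------------------------------
# Detector


class Detector:
    """Backbone (stride 96) + 5-channel head with fixed output activations."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        g = config.growth_rate
        layers: list = [Conv2d(1, 2 * g, 3, rng), ReLU(), AvgPool(POOL_FACTORS[0])]
        c = 2 * g
        for i, n_layers in enumerate(config.blocks):
            block = DenseBlock(c, n_layers, g, rng)
            layers.append(block)
            layers.append(Conv2d(block.cout, 2 * g, 1, rng))  # transition
            layers.append(ReLU())
            layers.append(AvgPool(POOL_FACTORS[i + 1]))
            c = 2 * g
        for f in POOL_FACTORS[len(config.blocks) + 1:]:
            layers.append(AvgPool(f))
        self.backbone = layers
        # head: near-zero weights + prior-matched confidence bias, so a fresh
        # model predicts background at ~1% confidence everywhere
        self.head = Conv2d(c, 5, 1, rng, weight_std=0.01)
        self.head.b[0] = -np.log((1.0 - CONFIDENCE_PRIOR) / CONFIDENCE_PRIOR)
        self._cache: dict | None = None

    def params(self):
        out = []
        for layer in self.backbone:
            out.extend(layer.params())
        out.extend(self.head.params())
        return out

    def forward(self, batch: np.ndarray, train: bool = False) -> list[DetectionGrid]:
        """Run slices (N, rows, cols) with dims multiples of 96 through the net."""
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 2:
            batch = batch[None]
        n, h, w = batch.shape
        if h % CELL or w % CELL:
            raise ValueError(f"input {h}x{w} must be a multiple of {CELL}; pad first")
        x = batch[:, None]
        for layer in self.backbone:
            x = layer.forward(x, train)
        z = self.head.forward(x, train)
        conf = 1.0 / (1.0 + np.exp(-z[:, 0]))
        off = 0.5 * np.tanh(z[:, 1:3])
        scale = z[:, 3:5]
        if train:
            self._cache = {"conf": conf, "off": off}
        reg = np.concatenate([off, scale], axis=1)
        return [DetectionGrid(confidence=conf[i], regression=reg[i]) for i in range(n)]

    def backward(self, d_conf: np.ndarray, d_reg: np.ndarray) -> None:
        """Backpropagate gradients given wrt confidence and regression outputs."""
        cache = self._cache
        conf, off = cache["conf"], cache["off"]
        dz = np.empty((d_conf.shape[0], 5) + d_conf.shape[1:], dtype=np.float32)
        dz[:, 0] = d_conf * conf * (1.0 - conf)
        dz[:, 1:3] = d_reg[:, 0:2] * 0.5 * (1.0 - 4.0 * off * off)
        dz[:, 3:5] = d_reg[:, 2:4]
        dx = self.head.backward(dz)
        for layer in reversed(self.backbone):
            dx = layer.backward(dx)
        self._cache = None

    def zero_grad(self) -> None:
        for _, grad in self.params():
            grad[...] = 0.0


def build_detector(config: DetectorConfig | None = None) -> Detector:
    return Detector(config or DetectorConfig())


def decode_predictions(grid: DetectionGrid, threshold: float) -> list[PredictedBox]:
    """One candidate box per cell with confidence above ``threshold``.

    Boxes are in the coordinates of the slice the grid was computed on;
    ``z`` is left at 0 for the caller to assign.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    out = []
    gr, gc = grid.confidence.shape
    for i in range(gr):
        for j in range(gc):
            score = float(grid.confidence[i, j])
            if score <= threshold:
                continue
            off_x, off_y, sw, sh = (float(v) for v in grid.regression[:, i, j])
            cx = (j + 0.5) * CELL + off_x * CELL
            cy = (i + 0.5) * CELL + off_y * CELL
            w, h = ANCHOR * np.exp(sw), ANCHOR * np.exp(sh)
            out.append(PredictedBox(x=cx - w / 2, y=cy - h / 2, width=w, height=h,
                                    z=0, score=min(score, 1.0)))
    return out


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(detector: Detector, path) -> None:
    arrays = {f"p{i}": p for i, (p, _) in enumerate(detector.params())}
    cfg = {"growth_rate": detector.config.growth_rate,
           "blocks": list(detector.config.blocks),
           "seed": detector.config.seed}
    np.savez(path, _config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Detector:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["_config"]).decode())
        det = Detector(DetectorConfig(growth_rate=cfg["growth_rate"],
                                      blocks=tuple(cfg["blocks"]), seed=cfg["seed"]))
        for i, (p, _) in enumerate(det.params()):
            p[...] = data[f"p{i}"]
    return det
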