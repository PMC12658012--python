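"""A 3D U-Net for volumetric binary segmentation, implemented in numpy.

The architecture is the classic encoder-decoder with skip connections:

* **encoder** — an initial convolution to ``base`` feature maps followed by
  four ``Conv + MaxPool + Conv`` blocks, doubling the feature maps at every
  pooling step, and a final convolution to ``32 * base`` maps.  Ten
  convolutional layers and four 2x2x2 max-pool layers in total; after the
  four pools the spatial grid is 1/16 of the input per axis.
* **decoder** — a convolution at the bottleneck, then four
  ``Conv + Upsample + Conv`` blocks mirroring the encoder.  Upsampling is
  plain element repetition by 2 per axis; encoder features at the matching
  resolution are concatenated after each upsample.  A final 3x3x3
  convolution reduces to one channel, and a sigmoid yields per-voxel
  foreground probabilities on the input grid.

All convolutions are 3x3x3 with same-padding, so the output grid equals the
input grid; every input axis must be divisible by 16.  With the default
``base = 16`` the encoder feature-map progression is
1-16-32-64-128-256-512.

Training uses a soft Dice loss and Adam, whole volumes at a time (batch
size 1) and no data augmentation.  Forward, backward and the optimizer are
written directly on numpy arrays, which keeps the package dependency-light
and the arithmetic fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .volume_io import ShapeError

DICE_EPS = 1e-6


class TransferError(ValueError):
    """Weight transfer between incompatible network specifications."""


# ---------------------------------------------------------------------------
# specification and weight containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Static description of the U-Net parameterization.

    ``base_channels`` scales the whole feature-map progression; 16 gives the
    reference 1-16-...-512 layout, smaller values give proportionally thinner
    networks for desk-scale experiments.  The layer graph itself (10 encoder
    convs, 4 pools, 4 upsamples) never changes.
    """

    in_channels: int = 1
    base_channels: int = 16
    levels: int = 5  # encoder resolution levels; levels - 1 pools

    @property
    def n_pools(self) -> int:
        return self.levels - 1

    @property
    def downsample_factor(self) -> int:
        return 2 ** self.n_pools

    def encoder_progression(self) -> list[int]:
        b = self.base_channels
        return [self.in_channels] + [b * 2 ** i for i in range(self.levels)] + [b * 2 ** self.levels]

    def layer_channels(self) -> dict[str, tuple[int, int]]:
        """Map layer name -> (in_channels, out_channels) for every conv."""
        b = self.base_channels
        ch: dict[str, tuple[int, int]] = {}
        ch["enc0"] = (self.in_channels, b)
        c = b
        for l in range(1, self.levels):
            ch[f"enc{l}a"] = (c, c)        # before pool
            ch[f"enc{l}b"] = (c, 2 * c)    # after pool: doubles the maps
            c *= 2
        ch["enc_deep"] = (c, 2 * c)        # bottleneck conv (e.g. 256 -> 512)
        deep = 2 * c
        ch["dec_deep"] = (deep, deep)
        c = deep
        for l in range(1, self.levels):
            skip = self.skip_channels()[l - 1]
            ch[f"dec{l}a"] = (c, c // 2)               # halve before upsampling
            ch[f"dec{l}b"] = (c // 2 + skip, c // 2)   # fuse the skip
            c //= 2
        ch["out"] = (c, 1)
        return ch

    def skip_channels(self) -> list[int]:
        # encoder tensors concatenated by decoder blocks 1..4, deep to shallow
        b = self.base_channels
        # enc outputs at R/8, R/4, R/2, R are enc4a(8b), enc3a(... wait see forward
        return [b * 2 ** (self.levels - 1 - l) for l in range(1, self.levels)]


@dataclass
class WeightState:
    """Ordered name -> parameter-array map plus provenance."""

    spec: NetworkSpec
    params: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def copy(self) -> "WeightState":
        return WeightState(self.spec, {k: v.copy() for k, v in self.params.items()},
                           dict(self.provenance))


@dataclass
class TrainConfig:
    lr: float = 3e-4
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 10
    batch_size: int = 1
    seed: int = 0
    clip_norm: float = 1.0  # global gradient-norm clip; 0 disables

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# primitive layers (forward + backward)
# ---------------------------------------------------------------------------

def _offsets():
    return [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3x3 convolution via shift-and-add GEMMs.

    One (C_out x C_in) matmul per kernel offset against the shifted input —
    faster than im2col for these kernel sizes and materializes no patch
    matrix.  w: (C_out, C_in, 3, 3, 3).
    """
    c_out, c_in = w.shape[:2]
    d, h, ww = x.shape[1:]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    y = np.empty((c_out, d * h * ww), dtype=np.float32)
    y[:] = b[:, None]
    wf = w.reshape(c_out, c_in, 27)
    for k, (dz, dy_, dx) in enumerate(_offsets()):
        xs = np.ascontiguousarray(xp[:, dz:dz + d, dy_:dy_ + h, dx:dx + ww]).reshape(c_in, -1)
        y += wf[:, :, k] @ xs
    return y.reshape(c_out, d, h, ww)


def conv3d_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray):
    """Gradients of a same-padded conv: returns (dx, dw, db)."""
    c_out, c_in = w.shape[:2]
    d, h, ww = x.shape[1:]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    dyf = dy.reshape(c_out, -1).astype(np.float32)
    dw = np.empty((c_out, c_in, 27), dtype=np.float32)
    for k, (dz, dy_, dx) in enumerate(_offsets()):
        xs = np.ascontiguousarray(xp[:, dz:dz + d, dy_:dy_ + h, dx:dx + ww]).reshape(c_in, -1)
        dw[:, :, k] = dyf @ xs.T
    db = dyf.sum(axis=1)
    # dx = conv of dy with channel-transposed, spatially flipped kernels
    w_flip = w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
    dx = conv3d(dy.astype(np.float32), np.ascontiguousarray(w_flip),
                np.zeros(c_in, dtype=np.float32))
    return dx, dw.reshape(w.shape), db


def maxpool2(x: np.ndarray):
    """2x2x2 max pooling; returns (y, argmax-cache)."""
    c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ShapeError(f"pooling requires even spatial dims, got {(d, h, w)}")
    xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    xr = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, shape = cache
    c, d, h, w = shape
    dxr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dxr = dxr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
    return dxr.reshape(c, d, h, w)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour x2 upsampling by element repetition per axis."""
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def dice_loss(prediction: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice loss ``1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)``."""
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ShapeError(f"prediction shape {p.shape} != target shape {t.shape}")
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def dice_loss_grad(prediction: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> np.ndarray:
    """d(dice_loss)/d(prediction), same shape as the prediction."""
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    inter = (p * t).sum()
    denom = p.sum() + t.sum() + eps
    num = 2.0 * inter + eps
    return (-2.0 * t * denom + num) / denom ** 2


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def build(spec: NetworkSpec = NetworkSpec(), seed: int = 0, stage: str = "") -> WeightState:
    """He-initialized weights for the given spec; deterministic per seed."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for name, (c_in, c_out) in spec.layer_channels().items():
        fan_in = c_in * 27
        params[f"{name}.W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3, 3)
        ).astype(np.float32)
        params[f"{name}.b"] = np.zeros(c_out, dtype=np.float32)
    return WeightState(spec, params, {"seed": seed, "stage": stage, "epochs": 0})


def validate_input_shape(shape: Sequence[int], factor: int = 16) -> None:
    for ax, s in enumerate(shape):
        if s % factor:
            raise ShapeError(
                f"input axis {ax} has size {s}, not divisible by {factor}"
            )


def _forward_cached(ws: WeightState, x: np.ndarray, need_cache: bool):
    """Run the network on (1, D, H, W) input; optionally keep the tape."""
    spec = ws.spec
    P = ws.params
    cache: dict = {"inputs": {}, "pool": {}, "relu": {}}

    def conv_relu(name, t, linear=False):
        if need_cache:
            cache["inputs"][name] = t
        y = conv3d(t, P[f"{name}.W"], P[f"{name}.b"])
        if linear:
            return y
        if need_cache:
            cache["relu"][name] = y > 0
        return relu(y)

    skips = []
    t = conv_relu("enc0", x)
    for l in range(1, spec.levels):
        t = conv_relu(f"enc{l}a", t)
        skips.append(t)
        t, pc = maxpool2(t)
        if need_cache:
            cache["pool"][l] = pc
        t = conv_relu(f"enc{l}b", t)
    t = conv_relu("enc_deep", t)
    t = conv_relu("dec_deep", t)
    for l in range(1, spec.levels):
        t = conv_relu(f"dec{l}a", t)
        t = upsample2(t)
        skip = skips[-l]
        t = np.concatenate([t, skip], axis=0)
        t = conv_relu(f"dec{l}b", t)
    logits = conv_relu("out", t, linear=True)
    if need_cache:
        # float64 keeps the sigmoid out of exact saturation, whose zero
        # gradient would otherwise be an absorbing state for Dice training
        prob = sigmoid(logits.astype(np.float64))
        cache["prob"] = prob
    else:
        prob = sigmoid(logits)
    return prob, cache


def forward(weights: WeightState, normalized_volume: np.ndarray) -> np.ndarray:
    """Per-voxel foreground probabilities for a [0, 1]-normalized volume.

    The volume shape must be divisible by 16 on every axis; the output has
    exactly the input shape with values in (0, 1).
    """
    x = np.asarray(normalized_volume, dtype=np.float32)
    if x.ndim != 3:
        raise ShapeError(f"expected a rank-3 volume, got rank {x.ndim}")
    validate_input_shape(x.shape, weights.spec.downsample_factor)
    prob, _ = _forward_cached(weights, x[None], need_cache=False)
    return prob[0]


def _backward(ws: WeightState, cache: dict, dprob: np.ndarray) -> dict[str, np.ndarray]:
    """Backpropagate d(loss)/d(prob) through the taped forward pass."""
    spec = ws.spec
    P = ws.params
    grads: dict[str, np.ndarray] = {}
    prob = cache["prob"]
    dt = (dprob * prob * (1.0 - prob)).astype(np.float32)

    def conv_back(name, dt, linear=False):
        if not linear:
            dt = dt * cache["relu"][name]
        dx, dw, db = conv3d_backward(cache["inputs"][name], P[f"{name}.W"], dt)
        grads[f"{name}.W"] = dw
        grads[f"{name}.b"] = db
        return dx

    dt = conv_back("out", dt, linear=True)
    dskips = {}
    for l in range(spec.levels - 1, 0, -1):
        dt = conv_back(f"dec{l}b", dt)
        n_up = P[f"dec{l}a.W"].shape[0]
        dup, dskip = dt[:n_up], dt[n_up:]
        dskips[spec.levels - 1 - l] = dskip  # gradient w.r.t. skips[-l]
        dt = upsample2_backward(dup)
        dt = conv_back(f"dec{l}a", dt)
    dt = conv_back("dec_deep", dt)
    dt = conv_back("enc_deep", dt)
    for l in range(spec.levels - 1, 0, -1):
        dt = conv_back(f"enc{l}b", dt)
        dt = maxpool2_backward(dt, cache["pool"][l])
        dt = dt + dskips[l - 1]
        dt = conv_back(f"enc{l}a", dt)
    conv_back("enc0", dt)
    return grads


def loss_and_grads(ws: WeightState, x: np.ndarray, target: np.ndarray):
    """Dice loss of one volume plus parameter gradients (for one SGD step)."""
    xf = np.asarray(x, dtype=np.float32)
    prob, cache = _forward_cached(ws, xf[None], need_cache=True)
    p = prob[0]
    loss = dice_loss(p, target)
    dp = dice_loss_grad(p, target)
    grads = _backward(ws, cache, dp[None])
    return loss, grads


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        b1, b2 = self.betas
        self.t += 1
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1 ** self.t)
            vh = self.v[k] / (1 - b2 ** self.t)
            params[k] -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(np.float32)


def train(train_samples, val_samples, config: TrainConfig,
          init_weights: Optional[WeightState] = None,
          spec: NetworkSpec = NetworkSpec(), stage: str = ""):
    """Train on whole volumes with Dice loss and Adam.

    ``train_samples`` / ``val_samples`` are sequences of ``(input, target)``
    arrays already resampled and normalized for the stage.  Returns the
    best-validation-loss checkpoint and the per-epoch loss history.
    """
    if not train_samples or not val_samples:
        raise ValueError("need at least one training and one validation sample")
    ws = init_weights.copy() if init_weights is not None else build(spec, seed=config.seed,
                                                                    stage=stage)
    for x, t in list(train_samples) + list(val_samples):
        validate_input_shape(x.shape, ws.spec.downsample_factor)
        if x.shape != t.shape:
            raise ShapeError("sample input and target shapes differ")
    ws.provenance = dict(ws.provenance, stage=stage, seed=config.seed)
    opt = Adam(ws.params, lr=config.lr, betas=config.betas)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, ws.copy())
    restarts = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_samples))
        ep_losses = []
        for i in order:
            x, t = train_samples[i]
            loss, grads = loss_and_grads(ws, x, t)
            if config.clip_norm > 0:
                gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
                if gnorm > config.clip_norm:
                    scale = config.clip_norm / gnorm
                    grads = {k: g * scale for k, g in grads.items()}
            opt.step(ws.params, grads)
            ep_losses.append(loss)
        val = float(np.mean([
            dice_loss(forward(ws, x), t) for x, t in val_samples
        ]))
        history["train_loss"].append(float(np.mean(ep_losses)))
        history["val_loss"].append(val)
        if val < best[0]:
            ws_best = ws.copy()
            ws_best.provenance["epochs"] = epoch + 1
            best = (val, ws_best)
        elif history["train_loss"][-1] > 0.995 and best[0] < 0.9 and restarts < 3:
            # the Dice empty-prediction state is absorbing: restore the best
            # checkpoint and continue more cautiously
            ws = best[1].copy()
            opt = Adam(ws.params, lr=opt.lr * 0.5, betas=config.betas)
            restarts += 1
    best[1].provenance.setdefault("epochs", config.epochs)
    return best[1], history


# ---------------------------------------------------------------------------
# Expansion Transfer Learning
# ---------------------------------------------------------------------------

def expansion_transfer(second_step_weights: WeightState,
                       target_spec: Optional[NetworkSpec] = None) -> WeightState:
    """Initialize a first-stage network from trained second-stage weights.

    The network is fully convolutional and therefore resolution-agnostic, so
    every parameter transfers verbatim; the refinement stage's detailed
    filters are expanded to the whole field of view.  The target spec must
    describe the identical layer inventory.
    """
    src = second_step_weights
    spec = target_spec or src.spec
    if spec.layer_channels() != src.spec.layer_channels():
        bad = [
            name for name in set(spec.layer_channels()) | set(src.spec.layer_channels())
            if spec.layer_channels().get(name) != src.spec.layer_channels().get(name)
        ]
        raise TransferError(f"incompatible layers: {sorted(bad)}")
    out = src.copy()
    out.provenance = {
        "init": "expansion_transfer",
        "source_stage": src.provenance.get("stage", "stage2"),
        "source_epochs": src.provenance.get("epochs"),
    }
    return out


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_weights(ws: WeightState, path: str | Path) -> None:
    """npz checkpoint with a JSON sidecar describing spec and provenance."""
    path = Path(path)
    np.savez(path, **ws.params)
    sidecar = {
        "spec": {"in_channels": ws.spec.in_channels,
                 "base_channels": ws.spec.base_channels,
                 "levels": ws.spec.levels},
        "provenance": ws.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_weights(path: str | Path) -> WeightState:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec(**sidecar["spec"])
    return WeightState(spec, {k: data[k] for k in data.files}, sidecar["provenance"])


def encoder_layer_inventory(spec: NetworkSpec = NetworkSpec()) -> dict[str, int]:
    """Count the encoder/decoder layers implied by the spec (for audits)."""
    names = list(spec.layer_channels())
    enc = [n for n in names if n.startswith("enc")]
    dec = [n for n in names if n.startswith("dec") or n == "out"]
    return {
        "encoder_convs": len(enc),
        "pools": spec.n_pools,
        "decoder_convs": len(dec),
        "upsamples": spec.n_pools,
        "deepest_feature_maps": spec.layer_channels()["enc_deep"][1],
    }
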