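"""Stage two: the fully convolutional heatmap-regression network.

Architecture (for net size ``n``, default 256):

* **Conv-1** — three 3x3 convolutions, stride 2 on the first; spatial
  size n -> n/2, channels 3 -> 32.
* **Bottleneck-1/2/3** — residual bottleneck blocks with 3 / 4 / 6
  bottleneck layers; each block halves the spatial size (stride 2 in its
  first layer) and the channel trace runs 32 -> 128 -> 256 -> 512.
* **Three deconvolution branches** — one per bottleneck block output,
  each a stack of stride-2 3x3 transposed convolutions (halving channels
  per step) followed by a 1x1 convolution to 2 channels, restoring the
  full n x n size.  Branch depths are 2/3/4 steps, the log2 of each
  block's downsampling factor.
* **Conv-2** — the three n x n x 2 branch outputs are concatenated to
  n x n x 6 and fused by two 3x3 convolutions (6 -> 16 -> 2).

Every convolution/deconvolution is followed by batch normalisation and
ReLU *except the final Conv-2 layer*, which is linear so the output can
regress the Gaussian label directly.  A bottleneck layer is
1x1 (compress to n_out/4) -> 3x3 (stride) -> 1x1 (expand to n_out) with
a shortcut that is the identity when shapes match and a strided 1x1
projection otherwise.

Training minimises pixel-wise mean squared error against the two-channel
Gaussian labels with Adam (learning rate 0.001); prediction takes the
per-channel argmax and maps it to crop-frame coordinates through the
crop/net scale of 2.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from . import nn
from .errors import ConfigError, InvalidInputError, ModelStateError
from .frames import CropWindow, LandmarkSet
from .heatmap import decode_heatmap


@dataclass(frozen=True)
class FCNConfig:
    """Complete architecture schedule of the stage-two network."""

    net_size: int = 256
    conv1_layers: int = 3
    conv1_out_channels: int = 32
    bottleneck_block_layer_counts: Tuple[int, int, int] = (3, 4, 6)
    bottleneck_block_out_channels: Tuple[int, int, int] = (128, 256, 512)
    conv2_layers: int = 2
    conv2_mid_channels: int = 16
    out_channels: int = 2
    bottleneck_reduction: int = 4
    width_multiplier: float = 1.0
    head_init_scale: float = 0.01   # final-layer weight scale at init
    seed: int = 0

    def __post_init__(self):
        if self.net_size % 16 != 0:
            raise ConfigError(
                f"net_size must be divisible by 16 (four x2 reductions), got {self.net_size}")
        ch = self.bottleneck_block_out_channels
        if not (ch[1] == 2 * ch[0] and ch[2] == 2 * ch[1]):
            raise ConfigError("channel schedule must double across Bottleneck-2 and -3")

    def width(self, c: int) -> int:
        """Apply the width multiplier to a reference channel count."""
        return max(2, int(round(c * self.width_multiplier)))

    @classmethod
    def tiny(cls, seed: int = 0) -> "FCNConfig":
        """64-net, quarter-width preset for CPU-scale experiments."""
        return cls(net_size=64, width_multiplier=0.25, seed=seed)


@dataclass(frozen=True)
class BottleneckSpec:
    n_in: int
    n_out: int
    stride: int = 1
    reduction: int = 4

    @property
    def internal_channels(self) -> int:
        return max(1, self.n_out // self.reduction)

    @property
    def identity_shortcut(self) -> bool:
        return self.n_in == self.n_out and self.stride == 1


def _conv_unit(cin, cout, k, stride, rng) -> nn.Sequential:
    return nn.Sequential([nn.Conv2d(cin, cout, k=k, stride=stride, rng=rng),
                          nn.BatchNorm2d(cout), nn.ReLU()])


def _deconv_unit(cin, cout, rng) -> nn.Sequential:
    return nn.Sequential([nn.ConvTranspose2d(cin, cout, rng=rng),
                          nn.BatchNorm2d(cout), nn.ReLU()])


class Bottleneck(nn.Layer):
    """Residual bottleneck: 1x1 compress, 3x3 (stride), 1x1 expand, add, ReLU."""

    def __init__(self, spec: BottleneckSpec, rng: np.random.Generator):
        self.spec = spec
        ic = spec.internal_channels
        self.c1 = nn.Conv2d(spec.n_in, ic, k=1, rng=rng)
        self.bn1, self.r1 = nn.BatchNorm2d(ic), nn.ReLU()
        self.c2 = nn.Conv2d(ic, ic, k=3, stride=spec.stride, rng=rng)
        self.bn2, self.r2 = nn.BatchNorm2d(ic), nn.ReLU()
        self.c3 = nn.Conv2d(ic, spec.n_out, k=1, rng=rng)
        self.bn3 = nn.BatchNorm2d(spec.n_out)
        # zero-gamma: the residual branch starts as identity, which speeds
        # early convergence markedly at small step budgets
        self.bn3.gamma.value[:] = 0.0
        if spec.identity_shortcut:
            self.shortcut = None
        else:
            self.sc_conv = nn.Conv2d(spec.n_in, spec.n_out, k=1,
                                     stride=spec.stride, pad=0, rng=rng)
            self.sc_bn = nn.BatchNorm2d(spec.n_out)
            self.shortcut = nn.Sequential([self.sc_conv, self.sc_bn])
        self.r_out = nn.ReLU()

    def params(self):
        ps = (self.c1.params() + self.bn1.params() + self.c2.params()
              + self.bn2.params() + self.c3.params() + self.bn3.params())
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def _atoms(self) -> List[nn.Layer]:
        atoms = [self.c1, self.bn1, self.c2, self.bn2, self.c3, self.bn3]
        if self.shortcut is not None:
            atoms += [self.sc_conv, self.sc_bn]
        return atoms

    def forward(self, x, train=True):
        if x.shape[1] != self.spec.n_in:
            raise InvalidInputError(
                f"bottleneck expects {self.spec.n_in} channels, got {x.shape[1]}")
        f = self.r1.forward(self.bn1.forward(self.c1.forward(x, train), train), train)
        f = self.r2.forward(self.bn2.forward(self.c2.forward(f, train), train), train)
        f = self.bn3.forward(self.c3.forward(f, train), train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.r_out.forward(s + f, train)

    def backward(self, dy):
        d = self.r_out.backward(dy)
        df = self.bn3.backward(d)
        df = self.c3.backward(df)
        df = self.r2.backward(df)
        df = self.bn2.backward(df)
        df = self.c2.backward(df)
        df = self.r1.backward(df)
        df = self.bn1.backward(df)
        dx = self.c1.backward(df)
        dx += d if self.shortcut is None else self.shortcut.backward(d)
        return dx


def bottleneck_forward(x: np.ndarray, spec: BottleneckSpec,
                       rng: Optional[np.random.Generator] = None,
                       train: bool = False) -> np.ndarray:
    """Run one freshly initialised bottleneck layer (testing convenience)."""
    return Bottleneck(spec, rng or np.random.default_rng(0)).forward(x, train=train)


class SkullFCN:
    """The full encoder / three-branch decoder network."""

    def __init__(self, config: FCNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.width
        c1 = w(config.conv1_out_channels)
        blocks_out = [w(c) for c in config.bottleneck_block_out_channels]
        out_ch = config.out_channels

        layers = [_conv_unit(3, c1, 3, 2, rng)]
        layers += [_conv_unit(c1, c1, 3, 1, rng) for _ in range(config.conv1_layers - 1)]
        self.conv1 = nn.Sequential(layers)

        self.blocks: List[nn.Sequential] = []
        n_in = c1
        for count, n_out in zip(config.bottleneck_block_layer_counts, blocks_out):
            specs = [BottleneckSpec(n_in if i == 0 else n_out, n_out,
                                    stride=2 if i == 0 else 1,
                                    reduction=config.bottleneck_reduction)
                     for i in range(count)]
            self.blocks.append(nn.Sequential([Bottleneck(s, rng) for s in specs]))
            n_in = n_out

        # branch i upsamples block i's output back to n x n, then 1x1 -> 2 ch
        self.branches: List[nn.Sequential] = []
        for i, bc in enumerate(blocks_out):
            steps = i + 2  # block spatial factors are n/4, n/8, n/16
            units: List[nn.Layer] = []
            ch = bc
            for _ in range(steps):
                nxt = max(out_ch, ch // 2)
                units.append(_deconv_unit(ch, nxt, rng))
                ch = nxt
            units.append(_conv_unit(ch, out_ch, 1, 1, rng))
            self.branches.append(nn.Sequential(units))

        c2m = w(config.conv2_mid_channels)
        head = nn.Conv2d(c2m, out_ch, k=3, stride=1, rng=rng)  # linear output
        # near-zero head: the initial output roughly matches the mostly-zero
        # Gaussian labels, which stabilises training across seeds
        head.W.value *= np.float32(config.head_init_scale)
        self.conv2 = nn.Sequential([_conv_unit(3 * out_ch, c2m, 3, 1, rng), head])
        self.trained = False

    # -- module plumbing -------------------------------------------------
    def modules(self) -> List[nn.Layer]:
        return [self.conv1, *self.blocks, *self.branches, self.conv2]

    def params(self) -> List[nn.Param]:
        return [p for m in self.modules() for p in m.params()]

    def _flat_layers(self) -> List[nn.Layer]:
        atoms: List[nn.Layer] = []
        for m in self.modules():
            for l in nn.flatten([m]):
                if isinstance(l, Bottleneck):
                    atoms.extend(l._atoms())
                else:
                    atoms.append(l)
        return atoms

    def get_state(self) -> List[np.ndarray]:
        return nn.get_state(self._flat_layers())

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        nn.set_state(self._flat_layers(), state)

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n = self.config.net_size
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != n or x.shape[3] != n:
            raise InvalidInputError(
                f"expected (N, 3, {n}, {n}) input, got {x.shape}")
        x1 = self.conv1.forward(x, train)
        b_outs = []
        h = x1
        for block in self.blocks:
            h = block.forward(h, train)
            b_outs.append(h)
        ys = [br.forward(b, train) for br, b in zip(self.branches, b_outs)]
        cat = np.concatenate(ys, axis=1)
        self._branch_channels = [y.shape[1] for y in ys]
        return self.conv2.forward(cat, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dcat = self.conv2.backward(dy)
        splits = np.cumsum(self._branch_channels)[:-1]
        dys = np.split(dcat, splits, axis=1)
        db = [br.backward(d) for br, d in zip(self.branches, dys)]
        # gradients flow into each block output from its branch and the next block
        grad = db[-1]
        for i in range(len(self.blocks) - 1, 0, -1):
            grad = self.blocks[i].backward(grad) + db[i - 1]
        dx1 = self.blocks[0].backward(grad)
        return self.conv1.backward(dx1)

    def spatial_trace(self) -> List[int]:
        """Spatial sizes after Conv-1 and each bottleneck block."""
        n = self.config.net_size
        return [n // 2, n // 4, n // 8, n // 16]


def build_fcn(config: Optional[FCNConfig] = None) -> SkullFCN:
    """Construct the network from an architecture schedule."""
    return SkullFCN(config or FCNConfig())


# ---- training ----------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule: MSE loss, Adam at the default 0.001."""

    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    keep_best: bool = True   # restore the best-validation-loss checkpoint
    eval_batch_size: int = 16


def _epoch_loss(model: SkullFCN, X: np.ndarray, Y: np.ndarray,
                batch: int) -> float:
    total, count = 0.0, 0
    for s in range(0, len(X), batch):
        pred = model.forward(X[s:s + batch], train=False)
        loss, _ = nn.mse_loss(pred, Y[s:s + batch])
        total += loss * len(pred)
        count += len(pred)
    return total / max(count, 1)


def train_fcn(train_pairs: Tuple[np.ndarray, np.ndarray],
              val_pairs: Tuple[np.ndarray, np.ndarray],
              train_config: Optional[TrainConfig] = None,
              model: Optional[SkullFCN] = None,
              fcn_config: Optional[FCNConfig] = None,
              ) -> Tuple[SkullFCN, Dict[str, list]]:
    """Fit the FCN on (images, labels) arrays in the net frame.

    ``train_pairs``/``val_pairs`` are ``(X, Y)`` with X ``(N, 3, n, n)``
    in [0, 1] and Y ``(N, 2, n, n)``.  Per-epoch mean training loss and
    validation loss are recorded; with ``keep_best`` the parameters of
    the best-validation epoch are restored at the end.  Fully
    deterministic given the seed.
    """
    cfg = train_config or TrainConfig()
    Xt, Yt = (np.ascontiguousarray(a, dtype=np.float32) for a in train_pairs)
    Xv, Yv = (np.ascontiguousarray(a, dtype=np.float32) for a in val_pairs)
    if Xt.shape[2:] != Yt.shape[2:]:
        raise InvalidInputError(f"image/label size mismatch {Xt.shape} vs {Yt.shape}")
    if model is None:
        model = build_fcn(fcn_config or FCNConfig(net_size=Xt.shape[2], seed=cfg.seed))
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))

    history: Dict[str, list] = {"train_loss": [], "val_loss": []}
    best = (np.inf, None, -1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xt))
        running, seen = 0.0, 0
        for s in range(0, len(Xt), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(Xt[idx], train=True)
            loss, grad = nn.mse_loss(pred, Yt[idx])
            model.backward(grad)
            opt.step()
            running += loss * len(idx)
            seen += len(idx)
        val = _epoch_loss(model, Xv, Yv, cfg.eval_batch_size)
        history["train_loss"].append(running / seen)
        history["val_loss"].append(val)
        if val < best[0]:
            best = (val, model.get_state(), epoch)
    if cfg.keep_best and best[1] is not None:
        model.set_state(best[1])
    history["best_epoch"] = best[2]
    model.trained = True
    return model, history


# ---- prediction --------------------------------------------------------

def predict_heatmap(model: SkullFCN, net_image: np.ndarray) -> np.ndarray:
    """Forward pass on one net-frame image; returns (n, n, 2)."""
    img = np.asarray(net_image, dtype=np.float32)
    if img.ndim == 3 and img.shape[2] == 3:
        img = img.transpose(2, 0, 1)
    if img.max() > 1.5:
        img = img / 255.0
    out = model.forward(img[None], train=False)[0]
    return np.moveaxis(out, 0, -1)


def predict_landmarks(model: SkullFCN, net_image: np.ndarray,
                      window: CropWindow, upscale_first: bool = False
                      ) -> LandmarkSet:
    """Predict bregma/lambda in the crop frame.

    By default the per-channel argmax is taken at net resolution and the
    coordinate scaled by crop/net (2.5).  With ``upscale_first`` the
    heatmap is bilinearly resized to the crop size before the argmax,
    reproducing the resize-then-argmax ordering; the two differ only by
    interpolation smoothing.
    """
    if not getattr(model, "trained", False):
        raise ModelStateError("model has not been trained or loaded")
    hm = predict_heatmap(model, net_image)
    if upscale_first:
        S = window.crop_size
        up = resize(hm, (S, S), order=1, anti_aliasing=False, preserve_range=True)
        return decode_heatmap(up, frame="crop")
    lm = decode_heatmap(hm, frame="net")
    b, l = window.net_to_crop(lm.bregma), window.net_to_crop(lm.lambda_)
    if tuple(b) == tuple(l):  # degenerate decode (e.g. constant output)
        return LandmarkSet.unchecked(b, l, "crop")
    return LandmarkSet(bregma=b, lambda_=l, frame="crop")


# ---- checkpointing -----------------------------------------------------

def save_checkpoint(path, model: SkullFCN, extra: Optional[dict] = None) -> None:
    """Single-file checkpoint: weights + config echo + metadata."""
    meta = {"config": asdict(model.config), "extra": extra or {}}
    state = model.get_state()
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(state)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> Tuple[SkullFCN, dict]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg_dict = dict(meta["config"])
    for key in ("bottleneck_block_layer_counts", "bottleneck_block_out_channels"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = build_fcn(FCNConfig(**cfg_dict))
    keys = sorted(k for k in data.files if k.startswith("arr_"))
    model.set_state([data[k] for k in keys])
    model.trained = True
    return model, meta["extra"]
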