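"""Encoder-decoder segmentation network as a pure numpy computational core.

The network follows the U-Net pattern: a four-level encoder
(3x3 convolution -> ReLU -> stride-2 max-pool), a mirrored decoder of
2x2 stride-2 transposed convolutions with optional encoder->decoder skip
concatenations, and a final 1x1 convolution to class logits followed by
softmax. An alternative downsampling mode replaces the pools with
stride-2 convolutions. All forward and backward passes are implemented
explicitly on numpy arrays (im2col-style windowed tensor contractions),
which keeps the model dependency-free, deterministic and cheap enough to
train on a single CPU; correctness of every gradient is established by
finite-difference checks in the test suite.

Array layout is ``(N, C, H, W)`` internally; the public
:meth:`UNet.forward` accepts a single ``(H, W)`` or ``(H, W, 3)`` image
and returns an ``(H, W, n_classes)`` probability map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateInputError, FormatError, ModelError, ParameterError
from .io import IGNORE

__all__ = [
    "SegModelConfig", "UNet", "build_model", "pixel_loss",
    "softmax_cross_entropy", "Adam", "save_model", "load_model",
]


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture hyperparameters.

    ``filters`` gives the per-level encoder channel counts (the decoder
    mirrors them); ``downsample`` selects stride-2 max-pooling after
    stride-1 convolutions (``"pool"``, default) or stride-2 convolutions
    with no pooling (``"stride"``); ``use_skips`` toggles the U-Net skip
    concatenations (disable to obtain the plain semantic-segmentation
    backbone used as a baseline).
    """

    n_conv_layers: int = 4
    kernel_size: int = 3
    stride: int = 2
    filters: tuple[int, ...] = (8, 16, 32, 64)
    n_classes: int = 2
    in_channels: int = 1
    use_skips: bool = True
    downsample: str = "pool"
    ignore_label: int = IGNORE
    dtype: str = "float32"

    def __post_init__(self):
        if self.n_conv_layers != len(self.filters):
            raise ParameterError(
                f"n_conv_layers ({self.n_conv_layers}) must equal "
                f"len(filters) ({len(self.filters)})"
            )
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ParameterError("kernel_size must be odd")
        if self.downsample not in {"pool", "stride"}:
            raise ParameterError(f"unknown downsample mode {self.downsample!r}")
        if self.in_channels not in {1, 3}:
            raise ParameterError("in_channels must be 1 or 3")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d:
    """Same-padded 2-D convolution (cross-correlation), optional stride."""

    def __init__(self, cin, cout, k, stride=1, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k, self.stride = k, stride
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, train=False):
        k, s, p = self.k, self.stride, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        out = np.tensordot(win, self.W, axes=([1, 4, 5], [1, 2, 3]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        out += self.b[None, :, None, None]
        if train:
            self._xp, self._xshape = xp, x.shape
        return out

    def backward(self, dout):
        k, s, p = self.k, self.stride, self.k // 2
        N, C, H, W = self._xshape
        xp = self._xp
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self.db = dout.sum(axis=(0, 2, 3))
        self.dW = np.tensordot(dout, win, axes=([0, 2, 3], [0, 2, 3]))
        # scatter strided output gradients back onto the stride-1 grid
        n_pos_h = H + 2 * p - k + 1
        n_pos_w = W + 2 * p - k + 1
        if s == 1:
            dup = dout
        else:
            dup = np.zeros((N, dout.shape[1], n_pos_h, n_pos_w), dtype=dout.dtype)
            dup[:, :, ::s, ::s] = dout
        dpad = np.pad(dup, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        win2 = sliding_window_view(dpad, (k, k), axis=(2, 3))
        wflip = self.W[:, :, ::-1, ::-1]
        dxp = np.tensordot(win2, wflip, axes=([1, 4, 5], [0, 2, 3]))
        dxp = dxp.transpose(0, 3, 1, 2)
        self._xp = None
        return np.ascontiguousarray(dxp[:, :, p:p + H, p:p + W]) if p else dxp


class ConvTranspose2x2:
    """2x2, stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin, cout, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * 4))
        self.W = rng.normal(0.0, scale, size=(cin, cout, 2, 2)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        t = np.tensordot(x, self.W, axes=([1], [0]))  # (N, H, W, F, 2, 2)
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(N, self.W.shape[1], 2 * H, 2 * W)
        out = np.ascontiguousarray(out)
        out += self.b[None, :, None, None]
        if train:
            self._x = x
        return out

    def backward(self, dout):
        x = self._x
        N, C, H, W = x.shape
        F = self.W.shape[1]
        dr = dout.reshape(N, F, H, 2, W, 2).transpose(0, 1, 2, 4, 3, 5)
        self.db = dout.sum(axis=(0, 2, 3))
        self.dW = np.tensordot(x, dr, axes=([0, 2, 3], [0, 2, 3]))
        dx = np.tensordot(dr, self.W, axes=([1, 4, 5], [1, 2, 3]))
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU:
    def __init__(self):
        self._mask = None

    params = {}

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, dout):
        d = dout * self._mask
        self._mask = None
        return d


class MaxPool2:
    """2x2, stride-2 max pooling (input sides must be even)."""

    def __init__(self):
        self._idx = None

    params = {}

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xr = x.reshape(N, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(N, C, Ho, Wo, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (N, C, H, W)
        return out

    def backward(self, dout):
        N, C, H, W = self._shape
        Ho, Wo = H // 2, W // 2
        g = np.zeros((N, C, Ho, Wo, 4), dtype=dout.dtype)
        np.put_along_axis(g, self._idx[..., None], dout[..., None], axis=-1)
        g = g.reshape(N, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(g.reshape(N, C, H, W))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class UNet:
    """Four-level encoder-decoder with optional skips; see module docstring."""

    def __init__(self, config: SegModelConfig | None = None, seed: int = 0):
        self.config = config or SegModelConfig()
        cfg = self.config
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(seed)
        L = cfg.n_conv_layers
        f = cfg.filters
        k = cfg.kernel_size
        pooled = cfg.downsample == "pool"

        self.encoder_convs: list[Conv2d] = []
        self.enc_relus: list[ReLU] = []
        self.pools: list[MaxPool2] = []
        cin = cfg.in_channels
        for i in range(L):
            stride = 1 if pooled else cfg.stride
            self.encoder_convs.append(Conv2d(cin, f[i], k, stride, rng, dtype))
            self.enc_relus.append(ReLU())
            if pooled:
                self.pools.append(MaxPool2())
            cin = f[i]

        # decoder level i upsamples from depth L-i to depth L-i-1 and (with
        # skips) concatenates the matching encoder feature map
        self.up_convs: list[ConvTranspose2x2] = []
        self.dec_convs: list[Conv2d] = []
        self.dec_relus: list[ReLU] = []
        self._skip_src: list[int | None] = []
        h_ch = f[L - 1]
        for i in range(L):
            out_ch = f[L - 2 - i] if i < L - 1 else f[0]
            self.up_convs.append(ConvTranspose2x2(h_ch, h_ch, rng, dtype))
            src = self._skip_source(i)
            skip_ch = f[src] if (cfg.use_skips and src is not None) else 0
            self._skip_src.append(src if (cfg.use_skips and src is not None) else None)
            self.dec_convs.append(Conv2d(h_ch + skip_ch, out_ch, k, 1, rng, dtype))
            self.dec_relus.append(ReLU())
            h_ch = out_ch
        self.head = Conv2d(h_ch, cfg.n_classes, 1, 1, rng, dtype)

    def _skip_source(self, dec_level: int) -> int | None:
        L = self.config.n_conv_layers
        if self.config.downsample == "pool":
            return L - 1 - dec_level  # pre-pool feature at matching resolution
        src = L - 2 - dec_level  # post-stride feature one level up
        return src if src >= 0 else None

    # -- parameter plumbing -------------------------------------------------

    def layers(self):
        return (self.encoder_convs + self.up_convs + self.dec_convs
                + [self.head])

    def parameters(self):
        """Ordered list of (layer, name, array) for the optimiser."""
        out = []
        for layer in self.layers():
            for name, arr in layer.params.items():
                out.append((layer, name, arr))
        return out

    def state_dict(self):
        return {f"p{i}_{name}": arr
                for i, (layer, name, arr) in enumerate(self.parameters())}

    def load_state_dict(self, state):
        for i, (layer, name, arr) in enumerate(self.parameters()):
            setattr(layer, name, state[f"p{i}_{name}"].astype(arr.dtype))

    # -- forward / backward -------------------------------------------------

    @property
    def _factor(self) -> int:
        return 2 ** self.config.n_conv_layers

    def forward_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a ``(N, C, H, W)`` batch; sides must be multiples of
        ``2**n_conv_layers`` (the public :meth:`forward` pads arbitrary sizes)."""
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise FormatError(
                f"expected (N, {self.config.in_channels}, H, W) input, got {x.shape}"
            )
        if x.shape[2] % self._factor or x.shape[3] % self._factor:
            raise ParameterError(
                f"batch sides must be multiples of {self._factor}, got {x.shape[2:]}"
            )
        x = x.astype(self.head.W.dtype, copy=False)
        pooled = self.config.downsample == "pool"
        h = x
        skips = []
        for i in range(self.config.n_conv_layers):
            h = self.encoder_convs[i].forward(h, train)
            h = self.enc_relus[i].forward(h, train)
            skips.append(h)
            if pooled:
                h = self.pools[i].forward(h, train)
        self._concat_ch = []
        for i in range(self.config.n_conv_layers):
            h = self.up_convs[i].forward(h, train)
            src = self._skip_src[i]
            if src is not None:
                sk = skips[src]
                self._concat_ch.append((sk.shape[1], h.shape[1]))
                h = np.concatenate([sk, h], axis=1)
            else:
                self._concat_ch.append(None)
            h = self.dec_convs[i].forward(h, train)
            h = self.dec_relus[i].forward(h, train)
        return self.head.forward(h, train)

    def backward_batch(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for the last ``train=True`` forward."""
        L = self.config.n_conv_layers
        pooled = self.config.downsample == "pool"
        skip_grads: dict[int, np.ndarray] = {}
        d = self.head.backward(dlogits)
        for i in reversed(range(L)):
            d = self.dec_relus[i].backward(d)
            d = self.dec_convs[i].backward(d)
            src = self._skip_src[i]
            if src is not None:
                c_skip, _ = self._concat_ch[i]
                skip_grads[src] = d[:, :c_skip]
                d = np.ascontiguousarray(d[:, c_skip:])
            d = self.up_convs[i].backward(d)
        for i in reversed(range(L)):
            if pooled:
                d = self.pools[i].backward(d)
            if i in skip_grads:
                d = d + skip_grads[i]
            d = self.enc_relus[i].backward(d)
            d = self.encoder_convs[i].backward(d)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one image.

        Accepts ``(H, W)`` (single channel) or ``(H, W, 3)`` matching the
        configured input channels; sides that are not multiples of
        ``2**n_conv_layers`` are reflection-padded and the output cropped
        back. Returns ``(H, W, n_classes)`` with per-pixel simplex rows.
        """
        image = np.asarray(image)
        if image.ndim == 2:
            chans = 1
            x = image[None, None]
        elif image.ndim == 3 and image.shape[2] in (1, 3):
            chans = image.shape[2]
            x = image.transpose(2, 0, 1)[None]
        else:
            raise FormatError(f"unsupported image shape {image.shape}")
        if chans != self.config.in_channels:
            raise FormatError(
                f"model expects {self.config.in_channels} channel(s), got {chans}"
            )
        H, W = image.shape[:2]
        m = self._factor
        ph = (-H) % m
        pw = (-W) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        logits = self.forward_batch(x, train=False)
        logits = logits[0, :, :H, :W]
        return np.ascontiguousarray(softmax(logits, axis=0).transpose(1, 2, 0))


def build_model(config: SegModelConfig | None = None, seed: int = 0) -> UNet:
    """Construct a seeded :class:`UNet` from a :class:`SegModelConfig`."""
    return UNet(config, seed)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          ignore_label: int = IGNORE):
    """Mean cross-entropy over non-ignored pixels, with its logit gradient.

    ``logits``: (N, K, H, W); ``labels``: (N, H, W) integers. Returns
    ``(loss, dlogits, n_correct, n_counted)``; ignored pixels contribute
    nothing to the value or the gradient.
    """
    counted = labels != ignore_label
    n = int(counted.sum())
    if n == 0:
        raise DegenerateInputError("all pixels carry the ignore label")
    p = softmax(logits, axis=1)
    safe_labels = np.where(counted, labels, 0)
    idx = safe_labels[:, None]
    p_true = np.take_along_axis(p, idx, axis=1)[:, 0]
    loss = float(-np.sum(np.log(np.maximum(p_true, 1e-7)) * counted) / n)
    onehot_grad = p.copy()
    np.put_along_axis(
        onehot_grad, idx,
        np.take_along_axis(onehot_grad, idx, axis=1) - 1.0, axis=1,
    )
    onehot_grad *= counted[:, None] / n
    pred = logits.argmax(axis=1)
    n_correct = int(((pred == labels) & counted).sum())
    return loss, onehot_grad.astype(logits.dtype), n_correct, n


def pixel_loss(probs: np.ndarray, labels: np.ndarray,
               ignore_label: int = IGNORE) -> float:
    """Mean of ``-log p(true class)`` over non-ignored pixels.

    ``probs`` is an ``(H, W, K)`` probability map, ``labels`` an ``(H, W)``
    label map with classes ``0..K-1`` plus the ignore label. Probabilities
    are clipped at 1e-7 inside the log.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.shape[:2] != labels.shape:
        raise FormatError(
            f"probs {probs.shape[:2]} and labels {labels.shape} differ in size"
        )
    counted = labels != ignore_label
    n = int(counted.sum())
    if n == 0:
        raise DegenerateInputError("all pixels carry the ignore label")
    safe = np.where(counted, labels, 0)
    p_true = np.take_along_axis(probs, safe[..., None], axis=-1)[..., 0]
    return float(-np.sum(np.log(np.maximum(p_true, 1e-7)) * counted) / n)


# ---------------------------------------------------------------------------
# optimiser and checkpoints
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, model: UNet, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ParameterError("learning rate must be > 0")
        self.model = model
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._m = [np.zeros_like(arr) for _, _, arr in model.parameters()]
        self._v = [np.zeros_like(arr) for _, _, arr in model.parameters()]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, (layer, name, arr) in enumerate(self.model.parameters()):
            g = getattr(layer, "d" + name)
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / bc1
            vhat = self._v[i] / bc2
            arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(arr.dtype)


_CKPT_VERSION = 1


def save_model(model: UNet, path) -> None:
    """Serialise weights (.npz) plus a JSON config sidecar (.json)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {"version": _CKPT_VERSION, "seg_model_config": asdict(model.config)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> UNet:
    path = Path(path)
    json_path = path.with_suffix(".json")
    npz_path = path.with_suffix(".npz")
    if not json_path.exists() or not npz_path.exists():
        raise ModelError(f"checkpoint {path} is missing its .npz/.json files")
    sidecar = json.loads(json_path.read_text())
    if sidecar.get("version") != _CKPT_VERSION:
        raise ModelError(f"unsupported checkpoint version {sidecar.get('version')}")
    cfg_dict = sidecar["seg_model_config"]
    cfg_dict["filters"] = tuple(cfg_dict["filters"])
    model = UNet(SegModelConfig(**cfg_dict))
    with np.load(npz_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
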