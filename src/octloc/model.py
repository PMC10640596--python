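"""Network head with partial pooling over a convolutional feature map.

The model maps a B-scan ``x`` to a collection of probabilities
``yhat`` of shape ``(1+C) x B``: row 0 is the probability that each of the
``B`` markers is present anywhere in the slice, rows ``1..C`` the probability
of presence in each of the ``C`` equal-width image columns.  A convolutional
backbone produces a feature map ``z`` (``D_z x H_z x W_z`` with ``W_z = C``);
the slice descriptor ``d_0 = [avg_pool(z), max_pool(z)]`` and the column
descriptors ``d_c = [avg_pool(z[:, :, c]), max_pool(z[:, :, c])]`` are pushed
through one shared affine map and a sigmoid, so the same classifier scores
the whole slice and every column.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .nn import Tensor, as_tensor, concat, conv2d

__all__ = [
    "HeadConfig",
    "Descriptor",
    "Prediction",
    "ConvBackbone",
    "ColumnHeadModel",
    "build_backbone",
    "partial_pool",
    "head_forward",
    "model_forward",
    "BACKBONES",
]

# name -> (in_channels, ((out_channels, stride), ...), kernel, pad).  Even
# kernels aligned with the stride make the extractor mirror-consistent, so
# the column outputs of a flipped image can be exactly the flipped column
# outputs (the symmetry the flip-consistency loss maintains).
BACKBONES: dict[str, tuple[int, tuple[tuple[int, int], ...], int, int]] = {
    # small stride-16 extractor for CPU experiments: 128 -> 8 columns
    "tiny": (1, ((24, 2), (48, 2), (64, 2), (64, 2)), 4, 1),
    # stride-32 extractor with the published feature geometry:
    # 512 x 512 input -> 1792 x 16 x 16 map, descriptors of length 3584
    "conv1792": (3, ((24, 2), (48, 2), (96, 2), (448, 2), (1792, 2)), 4, 1),
}


@dataclass(frozen=True)
class HeadConfig:
    """Architecture hyper-parameters.

    ``n_columns`` must equal the width of the backbone's feature map for the
    configured ``image_size``; ``feature_channels`` is ``D_z``.
    """

    n_markers: int = 2
    n_columns: int = 16
    feature_channels: int = 1792
    backbone_name: str = "conv1792"
    image_size: int = 512
    hidden: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in ("n_markers", "n_columns", "feature_channels", "image_size"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        object.__setattr__(self, "hidden", tuple(self.hidden))

    @classmethod
    def tiny(cls, n_markers: int = 2, image_size: int = 128) -> "HeadConfig":
        return cls(
            n_markers=n_markers,
            n_columns=image_size // 16,
            feature_channels=64,
            backbone_name="tiny",
            image_size=image_size,
        )


@dataclass
class Descriptor:
    """Pooled descriptors: ``d0`` (batch x 2D_z) and ``dc`` (batch x C x 2D_z).

    The first ``D_z`` entries of each descriptor are spatial averages, the
    last ``D_z`` spatial maxima of the pooled region.
    """

    d0: Tensor
    dc: Tensor


class Prediction:
    """The ``(1+C) x B`` probability collection (optionally batched)."""

    def __init__(self, yhat: Tensor | np.ndarray):
        self.yhat = as_tensor(yhat)

    @property
    def array(self) -> np.ndarray:
        return self.yhat.data

    @property
    def n_columns(self) -> int:
        return self.yhat.shape[-2] - 1

    @property
    def n_markers(self) -> int:
        return self.yhat.shape[-1]

    def slice_probs(self) -> np.ndarray:
        """Row 0: probability of marker presence anywhere in the slice."""
        return self.array[..., 0, :]

    def column_probs(self) -> np.ndarray:
        """Rows 1..C: per-column marker probabilities (shape ... x C x B)."""
        return self.array[..., 1:, :]


def partial_pool(z: Tensor | np.ndarray) -> Descriptor:
    """Average+max pooling over the whole map and over each column.

    ``z`` has shape ``(N, D_z, H_z, W_z)`` (or unbatched ``(D_z, H_z, W_z)``);
    ``W_z`` is the column count.  No learned parameters.
    """
    z = as_tensor(z)
    if not np.all(np.isfinite(z.data)):
        raise ValueError("feature map contains non-finite values")
    if z.ndim == 3:
        z = z.reshape(1, *z.shape)
    n, d, h, w = z.shape
    d0 = concat([z.mean(axis=(2, 3)), z.reshape(n, d, h * w).amax(axis=2)], axis=-1)
    zc = z.transpose(0, 3, 1, 2)  # N, C, D, H
    dc = concat([zc.mean(axis=3), zc.amax(axis=3)], axis=-1)
    return Descriptor(d0=d0, dc=dc)


def head_forward(desc: Descriptor, weights: list[Tensor]) -> Prediction:
    """Apply the shared affine map (plus sigmoid) to d0 and every d_c.

    ``weights`` alternates (W, b) pairs; the default head is a single affine
    layer ``2 D_z -> B``.  The same parameters score the slice descriptor and
    all column descriptors, which is what lets slice-level supervision reach
    the columns.
    """
    if len(weights) % 2 != 0 or not weights:
        raise ValueError("weights must be (W, b) pairs")
    if weights[0].shape[0] != desc.d0.shape[-1]:
        raise ValueError(
            f"affine expects input {weights[0].shape[0]}, descriptor has {desc.d0.shape[-1]}"
        )

    def mlp(t: Tensor) -> Tensor:
        for i in range(0, len(weights), 2):
            t = t @ weights[i] + weights[i + 1]
            if i + 2 < len(weights):
                t = t.relu()
        return t

    logits0 = mlp(desc.d0)  # N x B
    logitsc = mlp(desc.dc)  # N x C x B
    n, b = logits0.shape
    yhat = concat([logits0.reshape(n, 1, b), logitsc], axis=1).sigmoid()
    return Prediction(yhat)


class ConvBackbone:
    """Plain stack of 4x4 stride-2 conv + ReLU blocks (NCHW).

    Fulfils the feature-extractor contract: image -> D_z x H_z x W_z map,
    exactly equivariant to horizontal flips.
    """

    def __init__(
        self,
        in_channels: int,
        blocks: tuple[tuple[int, int], ...],
        rng: np.random.Generator,
        kernel: int = 4,
        pad: int = 1,
        mirror_paired: bool = True,
    ):
        self.in_channels = in_channels
        self.blocks = blocks
        self.kernel = kernel
        self.pad = pad
        self.mirror_paired = mirror_paired
        self.params: list[Tensor] = []
        cin = in_channels
        first = True
        for cout, _stride in blocks:
            fan_in = cin * kernel * kernel
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel)).astype(np.float32)
            if mirror_paired and cout % 2 == 0:
                # channel 2i+1 is the horizontal mirror of channel 2i (input
                # channels pair-swapped in deeper layers), which makes the
                # extractor exactly flip-equivariant at initialization —
                # the symmetry the flip-consistency loss maintains
                wm = w[0::2, :, :, ::-1]
                if not first and cin % 2 == 0:
                    wm = wm.reshape(cout // 2, cin // 2, 2, kernel, kernel)[:, :, ::-1].reshape(cout // 2, cin, kernel, kernel)
                w[1::2] = wm
            self.params.append(Tensor(w, requires_grad=True))
            self.params.append(Tensor(np.ones(cout, dtype=np.float32), requires_grad=True))  # norm scale
            self.params.append(Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True))  # norm shift
            cin = cout
            first = False

    @property
    def out_channels(self) -> int:
        return self.blocks[-1][0]

    @property
    def reduction(self) -> int:
        r = 1
        for _, s in self.blocks:
            r *= s
        return r

    def forward(self, x: Tensor) -> Tensor:
        t = x
        for i in range(len(self.blocks)):
            stride = self.blocks[i][1]
            w, gamma, beta = self.params[3 * i : 3 * i + 3]
            t = conv2d(t, w, None, stride=stride, pad=self.pad)
            # instance norm: per-sample, per-channel standardization keeps
            # activations well-scaled whatever the input statistics, is
            # identical at train and test time, and commutes with flips
            c = t.shape[1]
            mu = t.mean(axis=(2, 3), keepdims=True)
            centered = t - mu
            var = (centered * centered).mean(axis=(2, 3), keepdims=True)
            t = centered / (var + 1e-5).sqrt()
            t = t * gamma.reshape(1, c, 1, 1) + beta.reshape(1, c, 1, 1)
            t = t.relu()
        return t


def build_backbone(name: str, rng: np.random.Generator) -> ConvBackbone:
    if name not in BACKBONES:
        raise KeyError(f"unknown backbone '{name}'; available: {sorted(BACKBONES)}")
    cin, blocks, kernel, pad = BACKBONES[name]
    return ConvBackbone(cin, blocks, rng, kernel=kernel, pad=pad)


class ColumnHeadModel:
    """Backbone + partial pooling + shared affine head."""

    def __init__(self, config: HeadConfig | None = None, seed: int = 0):
        self.config = config or HeadConfig()
        rng = np.random.default_rng(seed)
        self.backbone = build_backbone(self.config.backbone_name, rng)
        if self.backbone.out_channels != self.config.feature_channels:
            raise ValueError(
                f"backbone '{self.config.backbone_name}' yields "
                f"{self.backbone.out_channels} channels, config says {self.config.feature_channels}"
            )
        if self.config.image_size % self.backbone.reduction != 0 or (
            self.config.image_size // self.backbone.reduction != self.config.n_columns
        ):
            raise ValueError(
                f"image_size {self.config.image_size} with stride {self.backbone.reduction} "
                f"gives a {self.config.image_size // self.backbone.reduction}-wide feature map, "
                f"but n_columns is {self.config.n_columns}"
            )
        self.head_params: list[Tensor] = []
        dz = self.config.feature_channels
        din = 2 * dz
        dims = list(self.config.hidden) + [self.config.n_markers]
        for k, dout in enumerate(dims):
            w = rng.normal(0.0, np.sqrt(1.0 / din), size=(din, dout)).astype(np.float32)
            if k == 0 and self.backbone.mirror_paired and dz % 2 == 0:
                # tie rows across mirror-paired channels (both pooling halves)
                # so the head is invariant to the pair swap a flip induces
                v = w.reshape(2, dz // 2, 2, dout)
                v[:, :, 1] = v[:, :, 0]
                w = v.reshape(din, dout)
            self.head_params.append(Tensor(w, requires_grad=True))
            self.head_params.append(Tensor(np.zeros(dout, dtype=np.float32), requires_grad=True))
            din = dout

    def parameters(self) -> list[Tensor]:
        return self.backbone.params + self.head_params

    # ------------------------------------------------------------ forward
    def prepare(self, images: np.ndarray) -> Tensor:
        """Normalize/resize a (N, H, W) or (H, W) grayscale batch to NCHW input."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.max() > 1.5:  # 8-bit input
            x = x / 255.0
        s = self.config.image_size
        if x.shape[1] != s or x.shape[2] != s:
            x = np.stack([_sk_resize(im, (s, s), preserve_range=True, anti_aliasing=True) for im in x]).astype(np.float32)
        x = np.repeat(x[:, None], self.backbone.in_channels, axis=1)
        return Tensor(x)

    def forward(self, x: Tensor) -> Prediction:
        z = self.backbone.forward(x)
        if z.shape[-1] != self.config.n_columns:
            raise ValueError(
                f"feature map width {z.shape[-1]} != configured n_columns {self.config.n_columns}"
            )
        return head_forward(partial_pool(z), self.head_params)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Probabilities (N, 1+C, B) for raw grayscale images (no gradients)."""
        return self.forward(self.prepare(images)).array.copy()

    # --------------------------------------------------------- checkpoint
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ColumnHeadModel":
        path = Path(path)
        cfg = HeadConfig(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in json.loads(path.with_suffix(".json").read_text()).items()})
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.parameters()):
                p.data = data[f"p{i}"].astype(np.float32)
        return model


def model_forward(model: ColumnHeadModel, images: np.ndarray) -> Prediction:
    """Full forward pass on raw grayscale images (keeps the gradient tape)."""
    return model.forward(model.prepare(images))
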