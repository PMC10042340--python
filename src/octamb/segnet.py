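"""Boundary-detection network and its training recipe.

An encoder-decoder with skip connections and a multi-dilation block,
built from vertical (7x1) convolutions so features respond to axial
brightness steps.  The head emits one logit plane per boundary layer;
a softmax over the depth axis turns each A-scan column into a
probability distribution over the boundary position.  Training uses
cross-entropy against one-hot truth depths with the AMSGrad optimizer,
with lateral quartering and flip/scale/rotation augmentation.

The backbone runs on pure NumPy (see :mod:`octamb._nn`), which keeps
training deterministic and CPU-friendly at phantom scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _nn
from ._nn import Tensor
from .errors import TrainingError, ValidationError
from .phantom import N_BOUNDARIES, BOUNDARY_NAMES, BScanSample

__all__ = [
    "ModelConfig",
    "AugmentConfig",
    "TrainConfig",
    "ProbabilityVolume",
    "BoundaryTrace",
    "BoundaryNet",
    "build_model",
    "flip_lr",
    "apply_augment",
    "augment_sample",
    "quarter_split",
    "train_model",
    "predict_probabilities",
    "extract_boundaries",
]


@dataclass(frozen=True)
class ModelConfig:
    input_depth: int = 128
    input_width: int = 64
    n_boundaries: int = N_BOUNDARIES
    base_channels: int = 16
    n_levels: int = 3
    vertical_kernel: tuple[int, int] = (7, 1)
    mdc_dilations: tuple[int, ...] = (1, 2, 4, 8)
    seed: int = 0

    @property
    def stride(self) -> int:
        return 2 ** (self.n_levels - 1)

    def validate(self) -> None:
        if self.n_boundaries != N_BOUNDARIES:
            raise ValidationError(f"n_boundaries must be {N_BOUNDARIES}")
        kh, kw = self.vertical_kernel
        if kw != 1 or kh % 2 != 1 or kh < 1:
            raise ValidationError("vertical_kernel must be (odd, 1)")
        if self.n_levels < 2 or self.base_channels < 1:
            raise ValidationError("n_levels >= 2 and base_channels >= 1 required")
        if len(set(self.mdc_dilations)) != len(self.mdc_dilations) or any(
            d < 1 for d in self.mdc_dilations
        ):
            raise ValidationError("mdc_dilations must be positive and distinct")
        for name, dim in (("depth", self.input_depth), ("width", self.input_width)):
            if dim % self.stride != 0:
                pad = self.stride - dim % self.stride
                raise ValidationError(
                    f"input_{name} {dim} not divisible by 2^(n_levels-1) = "
                    f"{self.stride}; pad by {pad} pixels or adjust n_levels"
                )


@dataclass(frozen=True)
class AugmentConfig:
    lr_flip: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_deg: float = 15.0
    quarter_split: bool = True

    def validate(self) -> None:
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValidationError("scale_range must satisfy 0 < lo <= hi")
        if self.rotation_deg < 0:
            raise ValidationError("rotation_deg must be nonnegative")

    @property
    def geometric(self) -> bool:
        lo, hi = self.scale_range
        return self.lr_flip or self.rotation_deg > 0 or lo != 1.0 or hi != 1.0


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "amsgrad"
    learning_rate: float = 1e-3
    batch_size: int = 5
    epochs: int = 10
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.optimizer.lower() != "amsgrad":
            raise ValidationError("only the amsgrad optimizer is supported")
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValidationError("batch_size, epochs >= 1 and learning_rate > 0")
        self.augmentation.validate()


@dataclass
class ProbabilityVolume:
    """p[x, z, l]: probability that boundary l lies at depth z in A-scan x."""

    p: np.ndarray  # (width, depth, n_boundaries)
    boundary_names: tuple[str, ...] = BOUNDARY_NAMES

    @property
    def width(self) -> int:
        return self.p.shape[0]

    @property
    def depth(self) -> int:
        return self.p.shape[1]

    def validate(self, tol: float = 1e-5) -> None:
        if self.p.ndim != 3 or self.p.shape[2] != len(self.boundary_names):
            raise ValidationError("probability volume must be (width, depth, 6)")
        if np.any(self.p < 0):
            raise ValidationError("probabilities must be nonnegative")
        sums = self.p.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > tol:
            raise ValidationError(
                f"depth distributions not normalized (max |sum-1| = "
                f"{np.max(np.abs(sums - 1.0)):.2e} > {tol})"
            )


@dataclass
class BoundaryTrace:
    depth: np.ndarray  # (n_boundaries, width) int


class BoundaryNet:
    """Encoder-decoder with vertical kernels and a multi-dilation block."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.trained = False
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        k = config.vertical_kernel[0]
        cs = [config.base_channels * 2**i for i in range(config.n_levels - 1)]
        cb = config.base_channels * 2 ** (config.n_levels - 1)
        self._enc_channels = cs
        self._bottleneck_channels = cb

        def conv_param(name: str, c_in: int, c_out: int, kk: int) -> None:
            std = np.sqrt(2.0 / (c_in * kk))
            self.params[name + ".w"] = Tensor(
                rng.normal(0.0, std, size=(c_out, c_in, kk))
            )
            self.params[name + ".b"] = Tensor(np.zeros(c_out))

        prev = 1
        for i, c in enumerate(cs):
            conv_param(f"enc{i}a", prev, c, k)
            conv_param(f"enc{i}b", c, c, k)
            prev = c
        for d in config.mdc_dilations:
            conv_param(f"mdc{d}", cs[-1], cb, k)
        above = cb
        for i in reversed(range(len(cs))):
            conv_param(f"dec{i}proj", above, cs[i], 1)
            conv_param(f"dec{i}", 2 * cs[i], cs[i], k)
            above = cs[i]
        conv_param("head", cs[0], config.n_boundaries, 1)

    def parameters(self) -> list[Tensor]:
        return [self.params[n] for n in sorted(self.params)]

    def _conv(self, x: Tensor, name: str, dilation: int = 1) -> Tensor:
        return _nn.conv2d_vert(
            x, self.params[name + ".w"], self.params[name + ".b"], dilation
        )

    def forward(self, x: np.ndarray) -> Tensor:
        """x: (N, 1, H, W) -> logits (N, n_boundaries, H, W)."""
        n, c, h, w = x.shape
        if c != 1:
            raise ValidationError("input must have a single channel")
        if h != self.config.input_depth:
            raise ValidationError(
                f"input depth {h} != model input_depth {self.config.input_depth}"
            )
        if w % self.config.stride:
            raise ValidationError(
                f"input width {w} not divisible by {self.config.stride}; "
                f"pad by {self.config.stride - w % self.config.stride} pixels"
            )
        t = Tensor(x)
        skips: list[Tensor] = []
        for i in range(len(self._enc_channels)):
            t = _nn.relu(self._conv(t, f"enc{i}a"))
            t = _nn.relu(self._conv(t, f"enc{i}b"))
            skips.append(t)
            t = _nn.maxpool2x2(t)
        acc: Tensor | None = None
        for d in self.config.mdc_dilations:
            branch = self._conv(t, f"mdc{d}", dilation=d)
            acc = branch if acc is None else _nn.add(acc, branch)
        t = _nn.relu(acc)
        for i in reversed(range(len(self._enc_channels))):
            t = self._conv(t, f"dec{i}proj")
            t = _nn.upsample2x2(t)
            t = _nn.concat_channels(t, skips[i])
            t = _nn.relu(self._conv(t, f"dec{i}"))
        return self._conv(t, "head")

    def save(self, path) -> None:
        arrays = {n: p.data for n, p in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
        )
        arrays["__trained__"] = np.array(int(self.trained))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "BoundaryNet":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["__config__"]).decode())
            cfg_dict["vertical_kernel"] = tuple(cfg_dict["vertical_kernel"])
            cfg_dict["mdc_dilations"] = tuple(cfg_dict["mdc_dilations"])
            model = cls(ModelConfig(**cfg_dict))
            for name in model.params:
                model.params[name] = Tensor(data[name])
            model.trained = bool(data["__trained__"]) if "__trained__" in data else False
        return model


def build_model(config: ModelConfig) -> BoundaryNet:
    """Instantiate a seeded, randomly initialized boundary network."""
    return BoundaryNet(config)


def flip_lr(sample: BScanSample) -> BScanSample:
    """Mirror a sample along the A-scan axis; labels are unchanged."""
    return BScanSample(
        image=sample.image[:, ::-1].copy(),
        truth_boundaries=sample.truth_boundaries[:, ::-1].copy(),
        layer_labels=sample.layer_labels.copy(),
    )


def apply_augment(
    sample: BScanSample, flip: bool, scale: float, rotation_deg: float
) -> BScanSample:
    """Apply an explicit flip / isotropic scale / rotation about center.

    The image is resampled bilinearly; truth boundary curves are mapped
    through the same similarity transform and re-interpolated on the
    integer A-scan grid, then minimally adjusted to stay strictly
    ordered and inside the frame.
    """
    out = flip_lr(sample) if flip else BScanSample(
        image=sample.image.copy(),
        truth_boundaries=sample.truth_boundaries.copy(),
        layer_labels=sample.layer_labels.copy(),
    )
    if scale == 1.0 and rotation_deg == 0.0:
        return out

    h, w = out.image.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # scipy convention: input_coord = A @ output_coord + offset
    a_inv = rot.T / scale
    offset = c - a_inv @ c
    img = ndimage.affine_transform(
        out.image, a_inv, offset=offset, order=1, mode="nearest"
    )
    np.clip(img, 0.0, 1.0, out=img)

    xs = np.arange(w, dtype=float)
    new_tb = np.empty_like(out.truth_boundaries)
    fwd = scale * rot
    for l in range(out.truth_boundaries.shape[0]):
        pts = np.stack([out.truth_boundaries[l] - c[0], xs - c[1]])  # (2, W)
        moved = fwd @ pts
        zs_new = moved[0] + c[0]
        xs_new = moved[1] + c[1]
        order = np.argsort(xs_new)
        new_tb[l] = np.interp(xs, xs_new[order], zs_new[order])

    if new_tb.min() > h - 2 or new_tb.max() < 1:
        raise ValidationError("augmentation pushed all boundaries out of frame")
    np.clip(new_tb, 0.5, h - 1.5, out=new_tb)
    for l in range(1, new_tb.shape[0]):  # restore strict ordering at clip sites
        new_tb[l] = np.maximum(new_tb[l], new_tb[l - 1] + 1e-3)
    return BScanSample(
        image=img, truth_boundaries=new_tb, layer_labels=out.layer_labels
    )


def augment_sample(
    sample: BScanSample, aug: AugmentConfig, seed: int
) -> BScanSample:
    """Draw a random flip/scale/rotation from ``aug`` and apply it."""
    aug.validate()
    rng = np.random.default_rng(seed)
    flip = bool(aug.lr_flip and rng.random() < 0.5)
    scale = float(rng.uniform(*aug.scale_range))
    angle = float(rng.uniform(-aug.rotation_deg, aug.rotation_deg))
    return apply_augment(sample, flip, scale, angle)


def quarter_split(sample: BScanSample) -> list[BScanSample]:
    """Cut a B-scan into 4 equal-width lateral tiles with sliced truth."""
    h, w = sample.image.shape
    if w % 4:
        raise ValidationError(f"width {w} not divisible by 4")
    q = w // 4
    return [
        BScanSample(
            image=sample.image[:, k * q : (k + 1) * q].copy(),
            truth_boundaries=sample.truth_boundaries[:, k * q : (k + 1) * q].copy(),
            layer_labels=sample.layer_labels.copy(),
        )
        for k in range(4)
    ]


def _encode_targets(sample: BScanSample, depth: int) -> np.ndarray:
    """One-hot target depths as integer indices (n_boundaries, width)."""
    return np.clip(np.rint(sample.truth_boundaries), 0, depth - 1).astype(np.int64)


def train_model(
    model: BoundaryNet,
    samples: list[BScanSample],
    cfg: TrainConfig,
) -> tuple[BoundaryNet, list[float]]:
    """Train in place with AMSGrad + cross-entropy; returns loss history.

    Samples are laterally quartered (when enabled) and geometrically
    augmented afresh each epoch with per-(epoch, tile) seeds, so runs
    are bit-reproducible for a fixed ``cfg.seed``.
    """
    cfg.validate()
    if not samples:
        raise ValidationError("train_model requires at least one sample")
    depth = model.config.input_depth

    base_tiles: list[BScanSample] = []
    for s in samples:
        if cfg.augmentation.quarter_split:
            base_tiles.extend(quarter_split(s))
        else:
            base_tiles.append(s)

    opt = _nn.AMSGrad(model.parameters(), lr=cfg.learning_rate)
    order_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    history: list[float] = []
    for epoch in range(cfg.epochs):
        if cfg.augmentation.geometric:
            tiles = [
                augment_sample(
                    t,
                    cfg.augmentation,
                    int(
                        np.random.SeedSequence(
                            [cfg.seed, 2, epoch, i]
                        ).generate_state(1)[0]
                    ),
                )
                for i, t in enumerate(base_tiles)
            ]
        else:
            tiles = base_tiles
        idx = order_rng.permutation(len(tiles))
        losses: list[float] = []
        for start in range(0, len(idx), cfg.batch_size):
            batch = [tiles[j] for j in idx[start : start + cfg.batch_size]]
            x = np.stack([b.image for b in batch])[:, None, :, :].astype(np.float32)
            t = np.stack([_encode_targets(b, depth) for b in batch])
            logits = model.forward(x)
            loss = _nn.softmax_depth_xent(logits, t)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lv)
        history.append(float(np.mean(losses)))
    model.trained = True
    return model, history


def predict_probabilities(model: BoundaryNet, image: np.ndarray) -> ProbabilityVolume:
    """Run inference on one B-scan image (depth x width, values in [0,1])."""
    if image.ndim != 2:
        raise ValidationError("image must be 2-D (depth, width)")
    logits = model.forward(image[None, None, :, :].astype(np.float32))
    probs = _nn.softmax_depth(logits.data.astype(np.float64))[0]  # (L, H, W)
    pv = ProbabilityVolume(p=np.ascontiguousarray(probs.transpose(2, 1, 0)))
    pv.validate()
    return pv


def extract_boundaries(pv: ProbabilityVolume) -> BoundaryTrace:
    """Argmax depth per (boundary, A-scan); ties go to the smallest depth."""
    pv.validate()
    return BoundaryTrace(depth=np.argmax(pv.p, axis=1).T.astype(np.int64))
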