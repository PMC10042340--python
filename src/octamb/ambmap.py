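"""En-face ambiguity maps: arrange, smooth, normalize, colorize.

Row s of a layer's map is the per-A-scan entropy of volume slice s, so
the map is a top-down (slice x A-scan) view of boundary ambiguity.
The fixed pipeline is raw -> Gaussian smoothing (sigma = 1) -> min-max
normalization to [0, 1] -> jet colorization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .ambiguity import EntropyProfile
from .errors import ValidationError
from .phantom import BOUNDARY_NAMES, N_BOUNDARIES

__all__ = [
    "EnfaceMap",
    "ColorMapSpec",
    "JET",
    "build_enface",
    "gaussian_smooth",
    "minmax_normalize",
    "apply_colormap",
    "make_enface_map",
]


@dataclass(frozen=True)
class ColorMapSpec:
    """Piecewise-linear scalar -> RGB map defined by anchor points."""

    name: str
    anchors: tuple[tuple[float, tuple[float, float, float]], ...]

    def validate(self) -> None:
        pos = [a[0] for a in self.anchors]
        if pos != sorted(pos) or pos[0] != 0.0 or pos[-1] != 1.0:
            raise ValidationError("colormap anchors must cover [0, 1] in order")


#: the classical jet anchor sequence (dark blue -> blue -> cyan ->
#: yellow -> red -> dark red)
JET = ColorMapSpec(
    name="jet",
    anchors=(
        (0.0, (0.0, 0.0, 0.5)),
        (0.125, (0.0, 0.0, 1.0)),
        (0.375, (0.0, 1.0, 1.0)),
        (0.625, (1.0, 1.0, 0.0)),
        (0.875, (1.0, 0.0, 0.0)),
        (1.0, (0.5, 0.0, 0.0)),
    ),
)


@dataclass
class EnfaceMap:
    """All pipeline stages of one layer's en-face ambiguity map."""

    raw: np.ndarray  # (n_slices, width)
    smoothed: np.ndarray
    normalized: np.ndarray
    rgb: np.ndarray  # (n_slices, width, 3) in [0, 1]
    layer: int
    norm_min: float
    norm_max: float

    @property
    def layer_name(self) -> str:
        return BOUNDARY_NAMES[self.layer]


def build_enface(profiles: Sequence[EntropyProfile], layer: int) -> np.ndarray:
    """Stack one layer's entropy rows in acquisition order: (S, W)."""
    if not profiles:
        raise ValidationError("build_enface requires at least one slice profile")
    if not 0 <= layer < N_BOUNDARIES:
        raise ValidationError(f"layer must be in [0, {N_BOUNDARIES})")
    widths = {p.width for p in profiles}
    if len(widths) > 1:
        raise ValidationError(f"inconsistent slice widths: {sorted(widths)}")
    for p in profiles:
        p.validate()
    return np.stack([p.e[:, layer] for p in profiles], axis=0)


def gaussian_smooth(grid: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """2-D isotropic Gaussian smoothing (truncate 4*sigma, reflect pad)."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValidationError("grid contains non-finite entries")
    return ndimage.gaussian_filter(grid, sigma=sigma, mode="reflect", truncate=4.0)


def minmax_normalize(grid: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1]; a constant grid maps to all zeros."""
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValidationError("grid contains non-finite entries")
    lo, hi = float(grid.min()), float(grid.max())
    if hi == lo:
        return np.zeros_like(grid)
    return (grid - lo) / (hi - lo)


def apply_colormap(grid: np.ndarray, spec: ColorMapSpec = JET) -> np.ndarray:
    """Map normalized scalars to RGB via linear anchor interpolation."""
    spec.validate()
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0.0 or grid.max() > 1.0:
        raise ValidationError("apply_colormap expects values in [0, 1]")
    pos = np.array([a[0] for a in spec.anchors])
    cols = np.array([a[1] for a in spec.anchors])
    rgb = np.empty(grid.shape + (3,), dtype=float)
    for ch in range(3):
        rgb[..., ch] = np.interp(grid, pos, cols[:, ch])
    return rgb


def make_enface_map(
    profiles: Sequence[EntropyProfile],
    layer: int,
    sigma: float = 1.0,
    spec: ColorMapSpec = JET,
) -> EnfaceMap:
    """Run the fixed pipeline raw -> smooth -> normalize -> colorize.

    The pre-normalization min/max are retained so raw entropy values
    remain recoverable from the normalized map.
    """
    raw = build_enface(profiles, layer)
    smoothed = gaussian_smooth(raw, sigma=sigma)
    normalized = minmax_normalize(smoothed)
    rgb = apply_colormap(normalized, spec)
    return EnfaceMap(
        raw=raw,
        smoothed=smoothed,
        normalized=normalized,
        rgb=rgb,
        layer=layer,
        norm_min=float(smoothed.min()),
        norm_max=float(smoothed.max()),
    )
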