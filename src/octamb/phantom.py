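"""Synthetic OCT B-scan phantoms with known boundary geometry.

A phantom B-scan is rendered as horizontal reflectivity bands separated
by six smooth boundary curves (ILM, NFL/GCL, IPL/INL, OPL/ONL, EZ,
RPE/BM), with an optional foveal pit indenting the inner boundaries,
multiplicative speckle noise, and injectable lesions that locally
displace, blur or de-contrast specific boundaries.  Every sample
carries exact ground-truth boundary depths and per-layer abnormality
labels, so the phantoms stand in for an expert-labeled clinical cohort.

All generation is deterministic given (config, lesions, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import ValidationError

__all__ = [
    "BOUNDARY_NAMES",
    "N_BOUNDARIES",
    "LESION_KINDS",
    "FovealPit",
    "PhantomConfig",
    "LesionSpec",
    "BScanSample",
    "VolumeSample",
    "generate_bscan",
    "generate_volume",
    "generate_cohort",
    "default_lesion_menu",
    "slice_seed",
    "lesion_span",
    "lesion_blob",
]

BOUNDARY_NAMES = ("ILM", "NFL/GCL", "IPL/INL", "OPL/ONL", "EZ", "RPE/BM")
N_BOUNDARIES = 6

#: boundary indices each lesion kind is allowed to perturb
LESION_KINDS: dict[str, frozenset[int]] = {
    "ERM": frozenset({0}),
    "EDEMA": frozenset({1, 2, 3}),
    "DRUSEN_PED": frozenset({4, 5}),
    "EZ_LOSS": frozenset({4}),
    "OPL_DISTORTION": frozenset({3}),
    "SRD": frozenset({4, 5}),
}

#: boundaries each kind perturbs by default (drives the labels):
#: EDEMA displaces IPL/INL and OPL/ONL and blurs NFL/GCL as well
#: (fluid scatter), so all three inner boundaries count as abnormal
_DEFAULT_TARGETS: dict[str, tuple[int, ...]] = {
    "ERM": (0,),
    "EDEMA": (1, 2, 3),
    "DRUSEN_PED": (4, 5),
    "EZ_LOSS": (4,),
    "OPL_DISTORTION": (3,),
    "SRD": (4,),
}

# default boundary depths as fractions of the axial extent
_DEPTH_FRACTIONS = (0.23, 0.31, 0.41, 0.53, 0.67, 0.75)
# reflectivity of the 7 bands delimited by the 6 boundaries
_DEFAULT_INTENSITIES = (0.05, 0.55, 0.42, 0.28, 0.15, 0.65, 0.25)
# how strongly the foveal pit indents each boundary (inner > outer)
_PIT_FACTORS = np.array([1.0, 0.85, 0.6, 0.3, 0.0, 0.0])


@dataclass(frozen=True)
class FovealPit:
    """Gaussian indentation of the inner boundaries around the fovea."""

    center_frac: float = 0.5
    depth_px: float = 10.0
    halfwidth_px: float = 20.0

    def validate(self) -> None:
        if not 0.0 <= self.center_frac <= 1.0:
            raise ValidationError("foveal pit center_frac must be in [0, 1]")
        if self.depth_px < 0 or self.halfwidth_px <= 0:
            raise ValidationError("foveal pit depth/halfwidth must be >= 0 / > 0")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, reflectivity and noise of the synthetic B-scans."""

    width_ascans: int = 256
    depth_pixels: int = 128
    n_boundaries: int = N_BOUNDARIES
    layer_mean_depths: tuple[float, ...] | None = None
    layer_intensities: tuple[float, ...] = _DEFAULT_INTENSITIES
    boundary_waviness_amplitude: float = 1.5
    foveal_pit: FovealPit = field(default_factory=FovealPit)
    speckle_noise_sd: float = 0.03
    edge_softness: float = 0.7
    seed: int = 0

    def resolved_depths(self) -> np.ndarray:
        """Mean boundary depths; defaults scale with ``depth_pixels``."""
        if self.layer_mean_depths is not None:
            return np.asarray(self.layer_mean_depths, dtype=float)
        return self.depth_pixels * np.asarray(_DEPTH_FRACTIONS)

    def validate(self) -> None:
        if self.width_ascans < 4 or self.depth_pixels < 8:
            raise ValidationError("phantom dimensions too small")
        if self.n_boundaries != N_BOUNDARIES:
            raise ValidationError(
                f"n_boundaries is fixed at {N_BOUNDARIES}, got {self.n_boundaries}"
            )
        depths = self.resolved_depths()
        if depths.shape != (N_BOUNDARIES,):
            raise ValidationError("layer_mean_depths must have 6 entries")
        if np.any(np.diff(depths) <= 0):
            raise ValidationError("layer_mean_depths must be strictly increasing")
        if depths[0] <= 0 or depths[-1] >= self.depth_pixels:
            raise ValidationError(
                "layer_mean_depths must lie strictly inside (0, depth_pixels)"
            )
        if len(self.layer_intensities) != N_BOUNDARIES + 1:
            raise ValidationError("layer_intensities must have 7 entries")
        if any(not 0.0 <= v <= 1.0 for v in self.layer_intensities):
            raise ValidationError("layer_intensities must be within [0, 1]")
        if self.boundary_waviness_amplitude < 0 or self.speckle_noise_sd < 0:
            raise ValidationError("waviness and noise SD must be nonnegative")
        if self.edge_softness <= 0:
            raise ValidationError("edge_softness must be positive")
        self.foveal_pit.validate()


@dataclass(frozen=True)
class LesionSpec:
    """A local perturbation of one or more boundary layers.

    ``amplitude`` is a displacement in pixels for shape-changing kinds
    (ERM, EDEMA, DRUSEN_PED, OPL_DISTORTION, SRD) and a contrast
    reduction in [0, 1] for EZ_LOSS.  ``blur_sd`` widens the boundary
    edge locally (pixels).  The lateral window is a raised-cosine taper
    with compact support |x - lateral_center| < 2 * lateral_halfwidth.
    """

    kind: str
    lateral_center: int
    lateral_halfwidth: int
    amplitude: float = 0.0
    blur_sd: float = 0.0
    target_boundaries: tuple[int, ...] | None = None

    def targets(self) -> tuple[int, ...]:
        if self.target_boundaries is not None:
            return tuple(sorted(self.target_boundaries))
        return _DEFAULT_TARGETS[self.kind]

    def validate(self, config: PhantomConfig) -> None:
        if self.kind not in LESION_KINDS:
            raise ValidationError(
                f"unknown lesion kind {self.kind!r}; expected one of "
                f"{sorted(LESION_KINDS)}"
            )
        if not 0 <= self.lateral_center < config.width_ascans:
            raise ValidationError(
                f"lesion lateral_center {self.lateral_center} outside image "
                f"width [0, {config.width_ascans})"
            )
        if self.lateral_halfwidth <= 0:
            raise ValidationError("lateral_halfwidth must be positive")
        if self.amplitude < 0 or self.blur_sd < 0:
            raise ValidationError("amplitude and blur_sd must be >= 0")
        bad = set(self.targets()) - LESION_KINDS[self.kind]
        if bad:
            raise ValidationError(
                f"target_boundaries {sorted(bad)} inconsistent with kind "
                f"{self.kind} (allowed: {sorted(LESION_KINDS[self.kind])})"
            )

    def active(self) -> bool:
        return self.amplitude > 0 or self.blur_sd > 0

    def window(self, width: int) -> np.ndarray:
        """Raised-cosine lateral weight, compactly supported."""
        x = np.arange(width, dtype=float)
        u = np.abs(x - self.lateral_center) / (2.0 * self.lateral_halfwidth)
        w = np.where(u < 1.0, 0.5 * (1.0 + np.cos(np.pi * np.minimum(u, 1.0))), 0.0)
        return w


@dataclass
class BScanSample:
    """One synthetic cross-section with ground truth."""

    image: np.ndarray  # (depth, width) float in [0, 1]
    truth_boundaries: np.ndarray  # (6, width) float depths
    layer_labels: np.ndarray  # (6,) bool

    @property
    def global_label(self) -> bool:
        return bool(self.layer_labels.any())

    def validate(self) -> None:
        h, w = self.image.shape
        if self.truth_boundaries.shape != (N_BOUNDARIES, w):
            raise ValidationError("truth_boundaries shape mismatch")
        if np.any(np.diff(self.truth_boundaries, axis=0) <= 0):
            raise ValidationError("truth boundaries are not strictly ordered")


@dataclass
class VolumeSample:
    """An ordered stack of B-scans sharing one configuration."""

    slices: list[BScanSample]
    config: PhantomConfig
    slice_index_axis: str = "slow-scan"

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def validate(self) -> None:
        shapes = {s.image.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValidationError("volume slices have inconsistent dimensions")


def _boundary_curves(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Lesion-free boundary depths (6, W): mean + waviness + foveal pit."""
    w = config.width_ascans
    x = np.arange(w, dtype=float)
    depths = np.tile(config.resolved_depths()[:, None], (1, w))

    amp = config.boundary_waviness_amplitude
    # low-frequency harmonics: 70% of the amplitude is shared by all
    # boundaries (retinal layers undulate coherently, which also keeps
    # thin layers from self-crossing) and 30% is per-boundary.  The rng
    # is consumed even when amp == 0 so downstream draws don't shift.
    freqs = rng.integers(1, 4, size=(N_BOUNDARIES + 1, 2))
    phases = rng.uniform(0, 2 * np.pi, size=(N_BOUNDARIES + 1, 2))
    weights = rng.uniform(0.3, 1.0, size=(N_BOUNDARIES + 1, 2))
    weights /= weights.sum(axis=1, keepdims=True)

    def harmonics(row: int) -> np.ndarray:
        out = np.zeros(w)
        for j in range(2):
            out += weights[row, j] * np.sin(
                2 * np.pi * freqs[row, j] * x / w + phases[row, j]
            )
        return out

    if amp > 0:
        shared = harmonics(N_BOUNDARIES)
        for l in range(N_BOUNDARIES):
            depths[l] += amp * (0.7 * shared + 0.3 * harmonics(l))

    pit = config.foveal_pit
    if pit.depth_px > 0:
        c = pit.center_frac * (w - 1)
        bump = np.exp(-0.5 * ((x - c) / pit.halfwidth_px) ** 2)
        depths += pit.depth_px * _PIT_FACTORS[:, None] * bump[None, :]
    return depths


def _check_ordering(depths: np.ndarray, config: PhantomConfig, context: str) -> None:
    gaps = np.diff(depths, axis=0)
    if gaps.min() < 0.5:
        l, x = np.unravel_index(np.argmin(gaps), gaps.shape)
        raise ValidationError(
            f"{context}: boundaries {l} and {l + 1} cross or touch at "
            f"A-scan {x} (gap {gaps[l, x]:.2f} px)"
        )
    if depths[0].min() < 1.0 or depths[-1].max() > config.depth_pixels - 2.0:
        raise ValidationError(f"{context}: boundaries leave the axial field of view")


def generate_bscan(
    config: PhantomConfig,
    lesions: Sequence[LesionSpec] = (),
    seed: int | None = None,
) -> BScanSample:
    """Render one B-scan; deterministic given (config, lesions, seed)."""
    config.validate()
    for les in lesions:
        les.validate(config)
    if seed is None:
        seed = config.seed

    ss = np.random.SeedSequence(seed)
    geom_seed, noise_seed = ss.spawn(2)
    depths = _boundary_curves(config, np.random.default_rng(geom_seed))
    _check_ordering(depths, config, "lesion-free geometry")

    h, w = config.depth_pixels, config.width_ascans
    x = np.arange(w, dtype=float)
    softness = np.full((N_BOUNDARIES, w), config.edge_softness)
    cscale = np.ones((N_BOUNDARIES, w))
    extras: list[tuple[str, np.ndarray, LesionSpec]] = []

    for les in lesions:
        win = les.window(w)
        a = les.amplitude
        if les.kind == "ERM":
            depths[0] += a * win * np.sin(2 * np.pi * x / 8.0)
            if a > 0:
                extras.append(("erm_membrane", win, les))
        elif les.kind == "EDEMA":
            depths[2] -= 0.5 * a * win
            depths[3] += 0.5 * a * win
            if a > 0:
                extras.append(("edema_cyst", win, les))
        elif les.kind == "DRUSEN_PED":
            depths[5] -= a * win
            depths[4] -= 0.8 * a * win
        elif les.kind == "EZ_LOSS":
            cscale[4] *= 1.0 - min(a, 1.0) * win
        elif les.kind == "OPL_DISTORTION":
            depths[3] += a * win * np.sin(2 * np.pi * x / 16.0)
        elif les.kind == "SRD":
            depths[4] -= a * win
            if a > 0:
                extras.append(("srd_fluid", win, les))
        for l in les.targets():
            softness[l] += les.blur_sd * win

    _check_ordering(depths, config, "lesioned geometry")

    z = np.arange(h, dtype=float)[:, None]  # (H, 1)
    intens = np.asarray(config.layer_intensities)
    img = np.full((h, w), intens[0])
    for l in range(N_BOUNDARIES):
        step = intens[l + 1] - intens[l]
        edge = expit((z - depths[l][None, :]) / softness[l][None, :])
        img += step * cscale[l][None, :] * edge
        if np.any(cscale[l] < 1.0):
            # contrast loss is local to the edge: the removed step is
            # recovered over a gradual ramp so deeper bands keep their
            # nominal reflectivity
            ramp = expit((z - depths[l][None, :]) / (softness[l][None, :] + 5.0))
            img += step * (1.0 - cscale[l])[None, :] * ramp

    for name, win, les in extras:
        if name == "erm_membrane":
            line_z = depths[0] - 3.0
            img += 0.25 * win[None, :] * np.exp(-0.5 * (z - line_z[None, :]) ** 2)
        elif name == "edema_cyst":
            mid = 0.5 * (depths[2] + depths[3])
            sz = max(1.0, 0.35 * les.amplitude)
            img -= (
                0.25
                * win[None, :]
                * np.exp(-0.5 * ((z - mid[None, :]) / sz) ** 2)
            )
        elif name == "srd_fluid":
            band = expit((z - depths[4][None, :]) / 1.0) - expit(
                (z - depths[5][None, :]) / 1.0
            )
            img -= 0.3 * win[None, :] * band

    np.clip(img, 0.0, 1.0, out=img)
    if config.speckle_noise_sd > 0:
        noise = np.random.default_rng(noise_seed).standard_normal((h, w))
        img *= 1.0 + config.speckle_noise_sd * noise
        np.clip(img, 0.0, 1.0, out=img)

    labels = np.zeros(N_BOUNDARIES, dtype=bool)
    for les in lesions:
        if les.active():
            labels[list(les.targets())] = True

    sample = BScanSample(image=img, truth_boundaries=depths, layer_labels=labels)
    sample.validate()
    return sample


def slice_seed(master_seed: int, slice_index: int) -> int:
    """Deterministic per-slice seed derived from a volume master seed."""
    return int(
        np.random.SeedSequence([master_seed, slice_index]).generate_state(1)[0]
    )


def generate_volume(
    config: PhantomConfig,
    lesion_field: Mapping[int, Sequence[LesionSpec]] | None,
    n_slices: int,
    seed: int,
) -> VolumeSample:
    """Render an ordered stack of B-scans with per-slice lesions."""
    if n_slices < 1:
        raise ValidationError("a volume needs at least one slice")
    lesion_field = lesion_field or {}
    for s in lesion_field:
        if not 0 <= s < n_slices:
            raise ValidationError(f"lesion_field slice {s} outside [0, {n_slices})")
    slices = [
        generate_bscan(config, lesion_field.get(s, ()), slice_seed(seed, s))
        for s in range(n_slices)
    ]
    vol = VolumeSample(slices=slices, config=config)
    vol.validate()
    return vol


def lesion_span(
    template: LesionSpec, slices: Sequence[int]
) -> dict[int, list[LesionSpec]]:
    """Apply an identical lesion to every listed slice."""
    return {int(s): [template] for s in slices}


def lesion_blob(
    template: LesionSpec,
    center_slice: int,
    halfwidth_slices: float,
    n_slices: int,
    min_scale: float = 0.25,
) -> dict[int, list[LesionSpec]]:
    """Taper a lesion across slices to form an en-face blob.

    Amplitude and blur scale with a raised cosine along the slice axis;
    slices whose scale falls below ``min_scale`` are left untouched.
    """
    out: dict[int, list[LesionSpec]] = {}
    for s in range(n_slices):
        u = abs(s - center_slice) / (2.0 * halfwidth_slices)
        if u >= 1.0:
            continue
        scale = 0.5 * (1.0 + np.cos(np.pi * u))
        if scale < min_scale:
            continue
        out[s] = [
            dataclasses.replace(
                template,
                amplitude=template.amplitude * scale,
                blur_sd=template.blur_sd * scale,
            )
        ]
    return out


def default_lesion_menu(config: PhantomConfig) -> list[LesionSpec]:
    """Lesion templates scaled to the phantom geometry."""
    w, h = config.width_ascans, config.depth_pixels
    hw = max(8, w // 16)
    zscale = h / 128.0
    return [
        LesionSpec("EZ_LOSS", w // 2, hw, amplitude=0.7, blur_sd=3.0 * zscale),
        LesionSpec("EDEMA", w // 2, hw, amplitude=6.0 * zscale, blur_sd=1.5 * zscale),
        LesionSpec("DRUSEN_PED", w // 2, hw, amplitude=5.0 * zscale, blur_sd=1.0 * zscale),
    ]


def generate_cohort(
    n_normal: int,
    n_diseased: int,
    lesion_menu: Sequence[LesionSpec],
    config: PhantomConfig,
    seed: int,
    return_lesions: bool = False,
):
    """A labeled cohort of single B-scans: normals first, then diseased.

    Each diseased sample draws 1-3 lesions from the menu with
    randomized lateral center and scaled amplitude/blur.  Reproducible
    by seed.  With ``return_lesions=True`` also returns the drawn
    lesion lists (empty for normals) for independent label audits.
    """
    if n_normal < 0 or n_diseased < 0:
        raise ValidationError("cohort sizes must be nonnegative")
    if n_diseased > 0 and not lesion_menu:
        raise ValidationError("n_diseased > 0 requires a nonempty lesion_menu")
    config.validate()
    for les in lesion_menu:
        les.validate(config)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0B0]))
    samples: list[BScanSample] = []
    drawn: list[list[LesionSpec]] = []

    for i in range(n_normal):
        samples.append(generate_bscan(config, (), slice_seed(seed, i)))
        drawn.append([])

    w = config.width_ascans
    for i in range(n_diseased):
        img_seed = slice_seed(seed, n_normal + i)
        for _attempt in range(20):
            k = int(rng.integers(1, 4))
            picks = rng.integers(0, len(lesion_menu), size=k)
            lesions = []
            for j in picks:
                t = lesion_menu[j]
                lo, hi = 2 * t.lateral_halfwidth, w - 1 - 2 * t.lateral_halfwidth
                if hi <= lo:
                    lo, hi = w // 4, 3 * w // 4
                lesions.append(
                    dataclasses.replace(
                        t,
                        lateral_center=int(rng.integers(lo, hi + 1)),
                        amplitude=t.amplitude * rng.uniform(0.6, 1.2),
                        blur_sd=t.blur_sd * rng.uniform(0.6, 1.2),
                    )
                )
            try:
                samples.append(generate_bscan(config, lesions, img_seed))
            except ValidationError:
                continue  # redraw: random amplitudes forced a crossing
            drawn.append(lesions)
            break
        else:
            raise ValidationError(
                "could not draw a valid lesion combination in 20 attempts"
            )

    if return_lesions:
        return samples, drawn
    return samples
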