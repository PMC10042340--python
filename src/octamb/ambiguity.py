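"""Per-A-scan boundary-detection entropy and ambiguity indices.

For each A-scan x and boundary layer l the network yields a probability
distribution p[x, z, l] over the boundary depth z.  Its Shannon entropy

    e[x, l] = -sum_z p[x, z, l] * log p[x, z, l]

quantifies how ambiguous the boundary position is at that A-scan.  The
ambiguity index of a layer is the mean entropy over the included
A-scans; the overall index averages the six per-layer indices.

The logarithm defaults to natural log (entropies in nats); base 2 is
available.  The 0*log(0) = 0 convention applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .phantom import N_BOUNDARIES
from .segnet import ProbabilityVolume

__all__ = [
    "EntropyProfile",
    "AmbiguityIndex",
    "ascan_entropy",
    "layer_ambiguity_index",
    "overall_ambiguity_index",
    "fovea_mask",
]

_LOG_CLAMP = 1e-12


@dataclass
class EntropyProfile:
    """e[x, l]: entropy of the boundary-depth distribution (nonnegative)."""

    e: np.ndarray  # (width, n_boundaries)
    log_base: str = "e"

    @property
    def width(self) -> int:
        return self.e.shape[0]

    def validate(self) -> None:
        if self.e.ndim != 2 or self.e.shape[1] != N_BOUNDARIES:
            raise ValidationError("entropy profile must be (width, 6)")
        if not np.all(np.isfinite(self.e)) or np.any(self.e < -1e-12):
            raise ValidationError("entropies must be finite and nonnegative")


@dataclass
class AmbiguityIndex:
    per_layer: np.ndarray  # (6,)
    overall: float
    n_ascans: int

    def validate(self) -> None:
        if self.per_layer.shape != (N_BOUNDARIES,):
            raise ValidationError("per_layer must have 6 entries")
        if not (
            self.per_layer.min() - 1e-12
            <= self.overall
            <= self.per_layer.max() + 1e-12
        ):
            raise ValidationError("overall index outside per-layer range")


def _entropy_of(p: np.ndarray, axis: int, log_base: str) -> np.ndarray:
    q = np.maximum(p, _LOG_CLAMP)  # clamp only inside the log: 0*log(0) -> 0
    h = -(p * np.log(q)).sum(axis=axis)
    if log_base == "2":
        h /= np.log(2.0)
    elif log_base != "e":
        raise ValidationError(f"log_base must be 'e' or '2', got {log_base!r}")
    return np.maximum(h, 0.0)


def ascan_entropy(
    pv: ProbabilityVolume, log_base: str = "e", tol: float = 1e-5
) -> EntropyProfile:
    """Entropy of every (A-scan, boundary) depth distribution."""
    pv.validate(tol=tol)
    ep = EntropyProfile(e=_entropy_of(pv.p, axis=1, log_base=log_base),
                        log_base=log_base)
    ep.validate()
    return ep


def _included(ep: EntropyProfile, mask) -> np.ndarray:
    if mask is None:
        return np.arange(ep.width)
    idx = np.asarray(sorted(set(int(i) for i in mask)), dtype=int)
    if idx.size == 0:
        raise ValidationError("A-scan mask must be nonempty")
    if idx.min() < 0 or idx.max() >= ep.width:
        raise ValidationError("A-scan mask indices out of range")
    return idx


def layer_ambiguity_index(
    ep: EntropyProfile, layer: int, mask=None
) -> float:
    """Mean entropy of one boundary layer over the included A-scans."""
    ep.validate()
    if not 0 <= layer < N_BOUNDARIES:
        raise ValidationError(f"layer must be in [0, {N_BOUNDARIES})")
    idx = _included(ep, mask)
    return float(ep.e[idx, layer].mean())


def overall_ambiguity_index(ep: EntropyProfile, mask=None) -> AmbiguityIndex:
    """Per-layer mean entropies and their average.

    With no mask every layer shares the same A-scan count, so the
    mean of the per-layer means equals the pooled mean over all
    (A-scan, layer) pairs.
    """
    ep.validate()
    idx = _included(ep, mask)
    per_layer = ep.e[idx, :].mean(axis=0)
    ai = AmbiguityIndex(
        per_layer=per_layer,
        overall=float(per_layer.mean()),
        n_ascans=int(idx.size),
    )
    ai.validate()
    return ai


def fovea_mask(width: int, exclude_halfwidth: int, center: int | None = None):
    """A-scan indices with a centered window excluded.

    The fovea inflates ambiguity even in healthy eyes; excluding a
    central window is an optional confound control (default off in all
    index computations).
    """
    if center is None:
        center = width // 2
    if exclude_halfwidth < 0:
        raise ValidationError("exclude_halfwidth must be nonnegative")
    idx = [
        x for x in range(width) if abs(x - center) > exclude_halfwidth
    ]
    if not idx:
        raise ValidationError("fovea mask excludes every A-scan")
    return idx
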