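"""File formats, run configuration, and output manifests.

Images travel as 8-bit grayscale BMP/PNG/TIFF (row 0 = shallowest
depth), tables as CSV, configuration and labels as JSON, probability
volumes as compressed ``.npz`` archives with a JSON header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field, is_dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .ambiguity import AmbiguityIndex, EntropyProfile
from .errors import FormatError, ValidationError
from .evalstats import StudySettings
from .phantom import (
    BOUNDARY_NAMES,
    N_BOUNDARIES,
    BScanSample,
    FovealPit,
    LesionSpec,
    PhantomConfig,
)
from .segnet import AugmentConfig, ModelConfig, ProbabilityVolume, TrainConfig

__all__ = [
    "read_bscan_image",
    "write_bscan_image",
    "write_probability_volume",
    "read_probability_volume",
    "write_cohort",
    "load_cohort",
    "write_entropy_csv",
    "ambiguity_summary",
    "write_outputs",
    "RunPaths",
    "RunConfig",
    "dataclass_from_dict",
]

_GRAYSCALE_MODES = {"L", "I", "I;16"}


def read_bscan_image(path) -> np.ndarray:
    """Load a grayscale B-scan as a (depth, width) float grid in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            if im.mode not in _GRAYSCALE_MODES:
                raise FormatError(
                    f"{path}: unsupported mode {im.mode!r}; expected 8-bit "
                    "grayscale (color or palette images are rejected)"
                )
            arr = np.asarray(im, dtype=float)
    except UnidentifiedImageError as exc:
        raise FormatError(f"{path}: not a readable image ({exc})") from exc
    except OSError as exc:
        raise FormatError(f"{path}: truncated or corrupt image ({exc})") from exc
    peak = 65535.0 if arr.max() > 255 else 255.0
    return arr / peak


def write_bscan_image(image: np.ndarray, path) -> Path:
    """Write intensities in [0, 1] as an 8-bit grayscale PNG/BMP/TIFF."""
    path = Path(path)
    if image.ndim != 2:
        raise ValidationError("image must be 2-D")
    q = np.clip(np.rint(np.asarray(image) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(q, mode="L").save(path)
    return path


def write_probability_volume(pv: ProbabilityVolume, path) -> Path:
    """Persist a probability volume as compressed npz + JSON header."""
    pv.validate()
    header = {
        "width_ascans": pv.width,
        "depth_pixels": pv.depth,
        "boundary_names": list(pv.boundary_names),
    }
    np.savez_compressed(
        path,
        p=pv.p,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
    )
    return Path(path)


def read_probability_volume(path) -> ProbabilityVolume:
    try:
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            pv = ProbabilityVolume(
                p=data["p"], boundary_names=tuple(header["boundary_names"])
            )
    except (OSError, KeyError, ValueError) as exc:
        raise FormatError(f"{path}: not a probability-volume file ({exc})") from exc
    pv.validate()
    return pv


def write_cohort(samples: Sequence[BScanSample], out_dir, config=None) -> dict:
    """Write a cohort: numbered PNGs, truth CSV and a JSON label sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    labels = []
    for i, s in enumerate(samples):
        write_bscan_image(s.image, out_dir / f"slice_{i:03d}.png")
        for l in range(N_BOUNDARIES):
            for x in range(s.truth_boundaries.shape[1]):
                rows.append((i, l, x, float(s.truth_boundaries[l, x])))
        labels.append(
            {
                "slice": i,
                "layer_labels": [bool(v) for v in s.layer_labels],
                "global_label": s.global_label,
            }
        )
    pd.DataFrame(
        rows, columns=["slice", "boundary_index", "x", "depth"]
    ).to_csv(out_dir / "truth.csv", index=False)
    sidecar = {
        "boundary_names": list(BOUNDARY_NAMES),
        "labels": labels,
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    (out_dir / "labels.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar


def load_cohort(data_dir) -> list[BScanSample]:
    """Re-read a cohort written by :func:`write_cohort`."""
    data_dir = Path(data_dir)
    sidecar_path = data_dir / "labels.json"
    if not sidecar_path.exists():
        raise FormatError(f"{data_dir}: missing labels.json sidecar")
    sidecar = json.loads(sidecar_path.read_text())
    truth = pd.read_csv(data_dir / "truth.csv")
    samples = []
    for entry in sidecar["labels"]:
        i = entry["slice"]
        image = read_bscan_image(data_dir / f"slice_{i:03d}.png")
        t = truth[truth["slice"] == i]
        width = image.shape[1]
        tb = np.empty((N_BOUNDARIES, width))
        for l in range(N_BOUNDARIES):
            tl = t[t["boundary_index"] == l].sort_values("x")
            tb[l] = tl["depth"].to_numpy()
        samples.append(
            BScanSample(
                image=image,
                truth_boundaries=tb,
                layer_labels=np.asarray(entry["layer_labels"], dtype=bool),
            )
        )
    return samples


def write_entropy_csv(profiles: Sequence[EntropyProfile], path) -> Path:
    """Entropy table with columns slice, boundary, x, entropy."""
    rows = []
    for s, ep in enumerate(profiles):
        for l in range(N_BOUNDARIES):
            for x in range(ep.width):
                rows.append((s, l, x, float(ep.e[x, l])))
    pd.DataFrame(rows, columns=["slice", "boundary", "x", "entropy"]).to_csv(
        path, index=False
    )
    return Path(path)


def ambiguity_summary(ai: AmbiguityIndex, log_base: str = "e") -> dict:
    return {
        "per_layer": {
            name: float(ai.per_layer[l]) for l, name in enumerate(BOUNDARY_NAMES)
        },
        "overall": float(ai.overall),
        "n_ascans": int(ai.n_ascans),
        "log_base": log_base,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    results: Mapping[str, Path | None],
    out_dir,
    seeds: Mapping[str, int] | None = None,
    config: Any = None,
) -> dict:
    """Write ``manifest.json`` listing every artifact with its checksum.

    Artifacts mapped to ``None`` are recorded as absent rather than
    silently omitted.  The manifest also records seeds, a hash of the
    run configuration, and library versions.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".octamb_write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"output directory not writable: {exc}") from exc

    artifacts: dict[str, Any] = {}
    for name in sorted(results):
        p = results[name]
        if p is None:
            artifacts[name] = {"absent": True}
        else:
            p = Path(p)
            artifacts[name] = {
                "path": str(p.relative_to(out_dir) if p.is_relative_to(out_dir) else p),
                "sha256": _sha256(p),
                "bytes": p.stat().st_size,
            }
    cfg_json = None
    if config is not None:
        cfg_dict = dataclasses.asdict(config) if is_dataclass(config) else config
        cfg_json = json.dumps(cfg_dict, sort_keys=True)
    import numpy, scipy  # noqa: PLC0415

    manifest = {
        "artifacts": artifacts,
        "seeds": dict(seeds or {}),
        "config_sha256": (
            hashlib.sha256(cfg_json.encode()).hexdigest() if cfg_json else None
        ),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
        "created": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# --- run configuration -------------------------------------------------

_TUPLE_FIELDS = {
    "layer_mean_depths",
    "layer_intensities",
    "vertical_kernel",
    "mdc_dilations",
    "scale_range",
    "target_boundaries",
}

_NESTED = {
    "foveal_pit": FovealPit,
    "augmentation": AugmentConfig,
    "phantom": PhantomConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "study": StudySettings,
    "paths": None,  # filled in below once RunPaths exists
}


def dataclass_from_dict(cls, d: Mapping[str, Any]):
    """Strictly build a config dataclass: unknown keys are rejected."""
    if not isinstance(d, Mapping):
        raise ValidationError(f"expected a mapping for {cls.__name__}, got {type(d)}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValidationError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)} "
            f"(valid keys: {sorted(names)})"
        )
    kwargs: dict[str, Any] = {}
    for key, value in d.items():
        nested_cls = _NESTED.get(key)
        if nested_cls is not None and isinstance(value, Mapping):
            kwargs[key] = dataclass_from_dict(nested_cls, value)
        elif key in _TUPLE_FIELDS and value is not None:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class RunPaths:
    data: str | None = None
    checkpoints: str | None = None
    outputs: str | None = None


_NESTED["paths"] = RunPaths


@dataclass(frozen=True)
class RunConfig:
    """One nested document configuring an end-to-end run."""

    seed: int = 0
    paths: RunPaths = field(default_factory=RunPaths)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    study: StudySettings = field(default_factory=StudySettings)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        return dataclass_from_dict(cls, d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
        return Path(path)
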