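"""Volumetric / planar image I/O and result-record serialization.

Volumes are multi-page grayscale TIFF stacks; the page index is the z axis and
arrays are ordered (z, y, x), matching the light-sheet stack convention.
Integer TIFFs are rescaled by the *dtype* maximum (255 for uint8, 65535 for
uint16), never by the per-image maximum, so a probability threshold means the
same thing for every image. Voxel spacing is always supplied explicitly by the
caller (in µm, order (z, y, x)); TIFF resolution tags are deliberately ignored
because their dialects are unreliable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ProbabilityVolume",
    "AxonMask",
    "PlanarImage",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_planar",
    "write_results",
    "read_results",
]

Spacing = tuple[float, float, float]


def _validate_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries (z, y, x), got {spacing!r}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing!r}")
    return spacing  # type: ignore[return-value]


@dataclass
class ProbabilityVolume:
    """A 3D per-voxel axon-probability field in [0, 1].

    Stand-in for the output of a 3D segmentation CNN; the pipeline only ever
    consumes such probability maps, it never runs the network.

    Parameters
    ----------
    data:
        3D float array, shape (z, y, x), every value in [0, 1].
    spacing:
        Voxel size in µm per axis, order (z, y, x), in post-expansion image
        space (i.e. not yet divided by the expansion factor).
    name:
        Free-text identifier carried through to result records.
    """

    data: np.ndarray
    spacing: Spacing
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = _validate_spacing(self.spacing)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("probability values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel, µm³."""
        return float(np.prod(self.spacing))

    @property
    def physical_volume_um3(self) -> float:
        """Physical volume of the whole field of view, µm³."""
        return float(np.prod(self.data.shape) * np.prod(self.spacing))


@dataclass
class AxonMask:
    """Binary axon segmentation with the provenance of how it was made."""

    data: np.ndarray
    spacing: Spacing
    threshold_used: float = float("nan")
    min_component_voxels: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def physical_volume_um3(self) -> float:
        return float(np.prod(self.data.shape) * np.prod(self.spacing))


@dataclass
class PlanarImage:
    """A single-channel 2D image (pre/post-expansion snapshot or max projection)."""

    data: np.ndarray
    pixel_size: float | Literal["unknown"] = "unknown"
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"planar image must be 2D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("planar image contains non-finite values")


def _rescale_to_unit(data: np.ndarray) -> np.ndarray:
    """Map integer dtypes to [0, 1] by the dtype maximum; clip floats to [0, 1]."""
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        out = data.astype(np.float64) / float(info.max)
    else:
        out = data.astype(np.float64)
    return np.clip(out, 0.0, 1.0)


def read_volume(path: str | Path, spacing: Sequence[float], name: str | None = None) -> ProbabilityVolume:
    """Read a multi-page TIFF stack as a probability volume.

    Pages map to z. Integer data are rescaled so that the dtype maximum becomes
    1.0; float data are clipped to [0, 1].
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale page stack, got shape {data.shape}")
    return ProbabilityVolume(_rescale_to_unit(data), _validate_spacing(spacing), name=name or path.stem)


def write_volume(volume: ProbabilityVolume, path: str | Path) -> None:
    """Write a probability volume as a 32-bit float multi-page TIFF."""
    tifffile.imwrite(Path(path), volume.data.astype(np.float32), photometric="minisblack")


def read_mask(path: str | Path, spacing: Sequence[float], name: str | None = None, **provenance: Any) -> AxonMask:
    """Read a binary mask stack (any nonzero voxel is foreground)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return AxonMask(data > 0, _validate_spacing(spacing), name=name or path.stem, **provenance)


def write_mask(mask: AxonMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit multi-page TIFF (foreground = 255)."""
    tifffile.imwrite(Path(path), mask.data.astype(np.uint8) * 255, photometric="minisblack")


def read_planar(path: str | Path, pixel_size: float | Literal["unknown"] = "unknown") -> PlanarImage:
    """Read a 2D grayscale TIFF/PNG image; multi-channel images are rejected."""
    path = Path(path)
    data = np.asarray(iio.imread(path))
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected single-channel 2D image, got shape {data.shape}")
    return PlanarImage(data.astype(np.float64), pixel_size=pixel_size, name=path.stem)


def _record_to_dict(record: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    if isinstance(record, dict):
        return dict(record)
    raise TypeError(f"cannot serialize record of type {type(record).__name__}")


def write_results(records: Sequence[Any], path: str | Path, format: Literal["csv", "json"] | None = None) -> None:
    """Serialize result records (dataclasses or dicts sharing one schema).

    CSV numbers keep 17 significant digits so a read-back reproduces every
    float bit-exactly.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    dicts = [_record_to_dict(r) for r in records]
    if len({tuple(d.keys()) for d in dicts}) > 1:
        raise ValueError("records do not share a single schema")
    if format == "json":
        path.write_text(json.dumps(dicts, indent=2, default=_json_default) + "\n")
    elif format == "csv":
        frame = pd.DataFrame(dicts)
        frame.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def read_results(path: str | Path) -> list[dict[str, Any]]:
    """Read back records written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    frame = pd.read_csv(path, float_precision="round_trip")
    return frame.to_dict(orient="records")
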