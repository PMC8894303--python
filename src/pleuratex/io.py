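"""Reading ultrasound frames and writing feature tables.

Frames arrive either as 8-bit greyscale DICOM files (single- or multi-frame
clips, the clinical acquisition format) or as plain PNG/TIFF images (used for
phantoms and fixtures).  Every frame is normalised to a :class:`GreyFrame`:
a 2-D integer array with values in [0, 255], row-major, origin at the
top-left, (row, column) indexing.

Colour inputs are collapsed to grey with the standard luma weights
(0.299 R + 0.587 G + 0.114 B) and rounded to the nearest integer.
DICOM ``MONOCHROME1`` data (higher value = darker) is inverted to
``MONOCHROME2`` semantics before analysis, because all texture formulas
assume brightness-increasing levels.  Vendor overlays and annotations are
not stripped; excluding them is the job of the ROI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UnsupportedFormatError, ValidationError

__all__ = [
    "GreyFrame",
    "ClipMeta",
    "ZONE_LABELS",
    "read_frames",
    "write_feature_table",
    "read_feature_table",
]

#: The 12 standard scan zones: side x (anterior|lateral|posterior) x (upper|lower).
ZONE_LABELS: tuple[str, ...] = tuple(
    f"{side}-{region}-{level}"
    for side in ("left", "right")
    for region in ("anterior", "lateral", "posterior")
    for level in ("upper", "lower")
)

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GreyFrame:
    """A single 8-bit greyscale frame.

    Parameters
    ----------
    pixels
        2-D integer array, values in [0, 255].
    source_id
        Label identifying provenance, conventionally ``"<file>#<frame index>"``.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"frame must be 2-D, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValidationError(f"frame must be at least 2x2, got {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.round(px)):
                raise ValidationError("frame pixels must be integers")
            px = px.astype(np.int64)
        if px.min() < 0 or px.max() > 255:
            raise ValidationError(
                f"pixel values must be in [0, 255], got range "
                f"[{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", np.ascontiguousarray(px, dtype=np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ClipMeta:
    """Metadata attached to one acquired clip (one subject, one zone)."""

    n_frames: int
    subject_id: str
    zone_id: str

    def __post_init__(self) -> None:
        if self.zone_id not in ZONE_LABELS:
            raise ValidationError(
                f"unknown zone_id {self.zone_id!r}; expected one of {ZONE_LABELS}"
            )
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


def _to_grey(arr: np.ndarray, source: str) -> np.ndarray:
    """Collapse trailing sample axis (RGB/RGBA) to grey by luma weights."""
    if arr.ndim == 3:
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[-1] == 3:
            arr = np.round(arr @ _LUMA)
        elif arr.shape[-1] == 1:
            arr = arr[..., 0]
        else:
            raise UnsupportedFormatError(
                f"{source}: unsupported sample count {arr.shape[-1]}"
            )
    if arr.min() < 0 or arr.max() > 255:
        raise UnsupportedFormatError(
            f"{source}: pixel values outside [0, 255] after grey conversion"
        )
    return np.round(arr).astype(np.uint8)


def _read_dicom(path: Path, frame_index: int | None) -> list[GreyFrame]:
    import pydicom

    ds = pydicom.dcmread(str(path))
    bits = int(getattr(ds, "BitsStored", getattr(ds, "BitsAllocated", 8)))
    has_rescale = hasattr(ds, "RescaleSlope") or hasattr(ds, "RescaleIntercept")
    arr = ds.pixel_array.astype(np.float64)
    if has_rescale:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
    elif bits > 8:
        raise UnsupportedFormatError(
            f"{path}: {bits}-bit pixel data without rescale information"
        )

    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames > 1:
        frames = [arr[i] for i in range(n_frames)]
    else:
        frames = [arr]

    if frame_index is not None:
        if not 0 <= frame_index < len(frames):
            raise ValidationError(
                f"{path}: frame_index {frame_index} out of range "
                f"(clip has {len(frames)} frames)"
            )
        frames = [frames[frame_index]]
        indices = [frame_index]
    else:
        indices = list(range(len(frames)))

    out = []
    for idx, fr in zip(indices, frames):
        grey = _to_grey(fr, str(path))
        if photometric == "MONOCHROME1":
            grey = (255 - grey.astype(np.int16)).astype(np.uint8)
        out.append(GreyFrame(grey, source_id=f"{path.name}#{idx}"))
    return out


def _read_image(path: Path, frame_index: int | None) -> list[GreyFrame]:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    # a multi-page TIFF comes back as (pages, h, w[, samples])
    if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] not in (1, 3, 4)):
        frames = [arr[i] for i in range(arr.shape[0])]
    else:
        frames = [arr]
    if frame_index is not None:
        if not 0 <= frame_index < len(frames):
            raise ValidationError(
                f"{path}: frame_index {frame_index} out of range"
            )
        indices = [frame_index]
        frames = [frames[frame_index]]
    else:
        indices = list(range(len(frames)))
    return [
        GreyFrame(_to_grey(fr.astype(np.float64), str(path)), source_id=f"{path.name}#{i}")
        for i, fr in zip(indices, frames)
    ]


def read_frames(path: str | Path, frame_index: int | None = None) -> list[GreyFrame]:
    """Read one or all frames from a DICOM clip or a PNG/TIFF image.

    Parameters
    ----------
    path
        DICOM (any extension; content-sniffed), PNG or TIFF file.
    frame_index
        If given, return only that frame (0-based); otherwise all frames.

    Returns
    -------
    list of GreyFrame
        One entry per requested frame, in acquisition order.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in {".png", ".tif", ".tiff"}:
        return _read_image(path, frame_index)
    if suffix in {".dcm", ".dicom", ""} or _looks_like_dicom(path):
        return _read_dicom(path, frame_index)
    raise UnsupportedFormatError(f"{path}: unrecognised image format")


def _looks_like_dicom(path: Path) -> bool:
    with open(path, "rb") as fh:
        fh.seek(128)
        return fh.read(4) == b"DICM"


def write_feature_table(
    records: Iterable[tuple[str, str, Mapping[str, float]]],
    path: str | Path,
) -> None:
    """Write ``(subject_id, zone_id, feature mapping)`` records to CSV.

    All records must share one feature-name set.  Floats are written with 17
    significant digits so a read-back round-trips to better than 12
    significant digits.
    """
    records = list(records)
    rows = []
    names: list[str] | None = None
    for subject_id, zone_id, feats in records:
        keys = list(feats.keys())
        if names is None:
            names = keys
        elif set(keys) != set(names):
            raise ValidationError(
                "inconsistent feature sets across records: "
                f"{sorted(names)} vs {sorted(keys)}"
            )
        rows.append({"subject_id": subject_id, "zone_id": zone_id, **{k: feats[k] for k in names}})
    if names is None:
        from .features import FEATURE_NAMES

        names = list(FEATURE_NAMES)
    df = pd.DataFrame(rows, columns=["subject_id", "zone_id", *names])
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path)
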