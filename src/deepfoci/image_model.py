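"""Core raster and annotation data types with file I/O.

Coordinate convention used throughout the package: 0-based pixel indices,
``x`` is the column index and ``y`` is the row index, pixel centers at
integer coordinates. Annotations and detections are point sets in this
convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

#: µm per pixel such that a 30 px radius corresponds to 128 µm.
DEFAULT_PIXEL_PITCH_UM = 128.0 / 30.0

Provenance = Literal["intensity", "gradient"]


class AnnotationFormatError(ValueError):
    """Raised when an annotation CSV is malformed or out of bounds."""


@dataclass
class TissueImage:
    """A single-channel wide-field fluorescence image of thick tissue.

    Parameters
    ----------
    pixels : ndarray
        2-D non-negative raster, ``float64`` internally.
    pixel_pitch_um : float
        Physical size of one pixel in µm (> 0).
    saturation_value : float
        Intensity at which the sensor clips; pixels at this value are
        considered saturated.
    bit_depth : int
        Nominal sensor bit depth.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    saturation_value: float | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("image raster must be 2-D with at least 2 rows and 2 columns")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.saturation_value is None:
            self.saturation_value = float(2**self.bit_depth - 1)
        peak = np.nanmax(self.pixels, initial=0.0)
        if peak > self.saturation_value:
            # float filtering can overshoot the ceiling by round-off; clip that
            if peak <= self.saturation_value * (1 + 1e-9):
                np.minimum(self.pixels, self.saturation_value, out=self.pixels)
            else:
                raise ValueError("pixel values exceed saturation_value")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def saturated_mask(self) -> np.ndarray:
        """Boolean raster of pixels clipped at the sensor ceiling."""
        return self.pixels >= self.saturation_value

    def contains_point(self, x: float, y: float) -> bool:
        h, w = self.pixels.shape
        return 0 <= x < w and 0 <= y < h


@dataclass
class ForegroundMask:
    """Boolean tissue-foreground raster paired with a TissueImage."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "ForegroundMask":
        return cls(np.ones(shape, dtype=bool))


@dataclass
class FociAnnotation:
    """Point annotations of foci centroids, in pixel coordinates (x, y)."""

    points: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CandidateSet:
    """Connected candidate regions over a parent image.

    ``labels`` is a 2-D int raster: 0 is background, positive integers are
    region ids. ``provenance`` maps each region id to the pipeline that
    produced it (``"intensity"`` or ``"gradient"``).
    """

    labels: np.ndarray
    provenance: dict[int, Provenance]
    parent_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != tuple(self.parent_shape):
            raise ValueError("label raster shape differs from parent image shape")
        ids = set(np.unique(self.labels)) - {0}
        if ids != set(self.provenance):
            raise ValueError("provenance keys must match region ids in the label raster")

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def region_pixels(self, region_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) index arrays of one region."""
        return np.nonzero(self.labels == region_id)

    def centroid(self, region_id: int) -> tuple[float, float]:
        """Region centroid as (x, y)."""
        rr, cc = self.region_pixels(region_id)
        return float(cc.mean()), float(rr.mean())

    @classmethod
    def empty(cls, parent_shape: tuple[int, int]) -> "CandidateSet":
        return cls(np.zeros(parent_shape, dtype=np.int32), {}, tuple(parent_shape))


@dataclass
class FocusRecord:
    """One candidate focus: centroid, region pixels, features and label."""

    centroid: tuple[float, float]
    region_id: int
    features: np.ndarray
    provenance: Provenance = "intensity"
    score: float = float("nan")
    label: Literal["positive", "negative"] = "negative"
    area_px: int = 0
    border_clipped: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=np.float64)
        if f.shape != (18,):
            raise ValueError("feature vector must have exactly 18 entries")
        if not np.all(np.isfinite(f)):
            raise ValueError("feature vector contains non-finite entries")
        self.features = f


def read_image(
    path: str | os.PathLike,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
    channel: str | int | None = "green",
    bit_depth: int | None = None,
) -> TissueImage:
    """Read a grayscale or RGB TIFF/PNG into a :class:`TissueImage`.

    Multi-channel inputs are reduced to one channel; by default the green
    channel is taken (EGFP emission lands there on an RGB camera). Pass an
    integer channel index or ``"red"/"green"/"blue"`` to override;
    ``channel=None`` on an RGB input raises a configuration error.
    """
    try:
        arr = iio.imread(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(f"multi-channel image {path!r} requires a channel policy")
        idx = {"red": 0, "green": 1, "blue": 2}.get(channel, channel)
        if not isinstance(idx, int) or not 0 <= idx < arr.shape[2]:
            raise ValueError(f"invalid channel {channel!r} for image with {arr.shape[2]} channels")
        arr = arr[:, :, idx]
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path!r}")
    if bit_depth is None:
        bit_depth = 8 * arr.dtype.itemsize if np.issubdtype(arr.dtype, np.integer) else 16
    return TissueImage(np.asarray(arr, dtype=np.float64), pixel_pitch_um=pixel_pitch_um, bit_depth=bit_depth)


def write_image(image: np.ndarray | TissueImage, path: str | os.PathLike) -> None:
    """Write a raster to TIFF (float rasters as 32-bit float, ints preserved)."""
    arr = image.pixels if isinstance(image, TissueImage) else np.asarray(image)
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    tifffile.imwrite(os.fspath(path), arr)


def read_annotations(
    path: str | os.PathLike,
    image_shape: tuple[int, int] | None = None,
    source: str = "",
) -> FociAnnotation:
    """Read a foci-centroid CSV with header columns ``x,y``.

    If ``image_shape`` is given, any out-of-bounds point raises an error
    naming the offending row (1-based data row number).
    """
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read annotation file {path!r}: {exc}") from exc
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise AnnotationFormatError(f"annotation file {path!r} lacks columns: {sorted(missing)}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise AnnotationFormatError(f"non-numeric {col!r} entry at data row {row} of {path!r}")
        df[col] = coerced
    pts = df[["x", "y"]].to_numpy(dtype=np.float64)
    if image_shape is not None:
        h, w = image_shape
        oob = (pts[:, 0] < 0) | (pts[:, 0] >= w) | (pts[:, 1] < 0) | (pts[:, 1] >= h)
        if oob.any():
            row = int(np.nonzero(oob)[0][0]) + 1
            raise AnnotationFormatError(f"point out of image bounds at data row {row} of {path!r}")
    return FociAnnotation(pts, source=source)


def write_annotations(annotation: FociAnnotation, path: str | os.PathLike) -> None:
    pd.DataFrame(annotation.points, columns=["x", "y"]).to_csv(path, index=False)


def write_detections(records: Sequence[FocusRecord], path: str | os.PathLike) -> None:
    """Write focus records to CSV with columns x, y, area_px, score, label."""
    rows = [
        {
            "x": r.centroid[0],
            "y": r.centroid[1],
            "area_px": r.area_px,
            "score": r.score,
            "label": r.label,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["x", "y", "area_px", "score", "label"])
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write detections to {path!r}: {exc}") from exc


def read_detections(path: str | os.PathLike) -> pd.DataFrame:
    """Read a detections CSV back as a DataFrame (columns x, y, area_px, score, label)."""
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise AnnotationFormatError(f"detections file {path!r} lacks columns: {sorted(missing)}")
    return df
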