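"""Raster image input and per-channel decomposition.

Fluorescence images arrive as 8-bit RGB rasters of a frond on a near-black
background.  All downstream analysis operates on the per-channel decimal
code values (DCV, the integer pixel intensity codes 0-255), so this module
is responsible for getting every input onto that scale and splitting it
into flat per-channel pixel sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Channel labels used throughout the pipeline.
CHANNELS = ("R", "G", "B")

#: ITU-R BT.601 luminance weights for the grayscale transform.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Columns required in a sample-metadata sidecar CSV.
METADATA_COLUMNS = (
    "source_id",
    "tray",
    "partition",
    "time_offset_h",
    "dose_nmol_per_cm2",
    "sample_type",
    "laser",
    "filter",
)


class ImageValidationError(ValueError):
    """Raised when an input image violates the 8-bit RGB contract."""


@dataclass
class RGBImage:
    """An 8-bit RGB raster: H x W x 3 integer DCVs in [0, 255]."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageValidationError(
                f"expected an H x W x 3 array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageValidationError("zero-area image")
        if not np.issubdtype(px.dtype, np.integer):
            raise ImageValidationError("pixel values must be integers")
        if px.min() < 0 or px.max() > 255:
            raise ImageValidationError("pixel values outside [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ChannelPixels:
    """Flat sequence of DCVs for one channel of one image.

    ``n_total`` records the pixel count before any thresholding so that
    downstream bookkeeping can verify conservation.
    """

    channel: str
    values: np.ndarray
    n_total: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64).ravel()
        if len(self.values) > self.n_total:
            raise ImageValidationError("more values than n_total")


def load_image(path: str | Path, source_id: str | None = None) -> RGBImage:
    """Read a PNG/TIFF raster and coerce it to 8-bit RGB.

    Higher bit depths are linearly rescaled to [0, 255]; single-channel
    images are replicated across R, G and B.  Both coercions log a warning
    because they change the DCV scale the pipeline reports.
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 2:
        logger.warning("%s: single-channel image replicated to RGB", path.name)
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        peak = info.max if info is not None else arr.max()
        logger.warning(
            "%s: %s input rescaled to 8-bit (peak %s)", path.name, arr.dtype, peak
        )
        arr = np.round(arr.astype(np.float64) * 255.0 / peak).astype(np.uint8)
    return RGBImage(pixels=arr.astype(np.int64), source_id=source_id or path.stem)


def split_channels(img: RGBImage) -> dict[str, ChannelPixels]:
    """Decompose an image into its R, G, B pixel sequences (raster order)."""
    n = img.height * img.width
    return {
        ch: ChannelPixels(
            channel=ch,
            values=img.pixels[:, :, k].ravel(),
            n_total=n,
            source_id=img.source_id,
        )
        for k, ch in enumerate(CHANNELS)
    }


def to_grayscale(img: RGBImage) -> ChannelPixels:
    """BT.601 weighted luminance, rounded half-up to integer DCV."""
    w = np.asarray(LUMA_WEIGHTS)
    lum = img.pixels.astype(np.float64) @ w
    gray = np.floor(lum + 0.5).astype(np.int64)  # round-half-up
    n = img.height * img.width
    return ChannelPixels(
        channel="GRAY", values=gray.ravel(), n_total=n, source_id=img.source_id
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata sidecar CSV, validating its schema."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ImageValidationError(
            f"metadata file {path} is missing columns: {', '.join(missing)}"
        )
    return df


@dataclass(frozen=True)
class FrondSample:
    """Metadata binding one image to its place in the experiment design.

    Negative ``time_offset_h`` marks a pre-dose control sampling; 0 is the
    moment of Cu dosing; 24 and 48 are the follow-up samplings.
    """

    sample_id: str
    tray: int
    partition: int
    time_offset_h: float
    dose_nmol_per_cm2: float
    sample_type: str = "single"  # single | pair | cuvette
    laser: str = ""
    filter: str = ""

    @property
    def is_control(self) -> bool:
        return self.time_offset_h < 0


def samples_from_metadata(df: pd.DataFrame) -> list[FrondSample]:
    """Turn a metadata sidecar table into FrondSample records."""
    return [
        FrondSample(
            sample_id=str(r.source_id),
            tray=int(r.tray),
            partition=int(r.partition),
            time_offset_h=float(r.time_offset_h),
            dose_nmol_per_cm2=float(r.dose_nmol_per_cm2),
            sample_type=str(r.sample_type),
            laser=str(r.laser),
            filter=str(r.filter),
        )
        for r in df.itertuples()
    ]
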