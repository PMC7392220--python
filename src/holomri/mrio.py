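"""Reading and writing MR inputs: DICOM series, grayscale rasters, masks.

Conventions used throughout the package:

* rasters are 2-D ``float`` arrays in [0, 1], row-major, origin top-left,
  (row, col) 0-based indices addressing pixel centres;
* a series is intensity-normalised per series (not per slice) so that the
  "brightest brain pixel" tumor-seeding rule is comparable across slices;
* masks are boolean arrays, written to disk as 8-bit PNG with {0, 255}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import yaml

from ._util import as_float_image


@dataclass
class MRSeries:
    """An ordered stack of grayscale slices with physical spacing metadata."""

    slices: list[np.ndarray]
    pixel_spacing: tuple[float, float]      # mm per pixel (row, col)
    slice_thickness: float                  # mm
    slice_separation: float                 # mm between slice centres
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a series needs at least one slice")
        shape = self.slices[0].shape
        bad = [i for i, s in enumerate(self.slices) if s.shape != shape]
        if bad:
            raise ValueError(f"slices {bad} differ in shape from slice 0 {shape}")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel_spacing must be positive")
        if not self.ids:
            self.ids = [f"slice-{i:03d}" for i in range(len(self.slices))]

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape


def read_dicom_series(directory: str | os.PathLike) -> MRSeries:
    """Read a directory of single-frame grayscale DICOM files as one series.

    Slices are sorted by their position along the scan axis (fallback:
    instance number), pixel values are rescaled by slope/intercept and then
    min-max normalised to [0, 1] over the whole series.
    """
    import pydicom

    directory = os.fspath(directory)
    paths = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".") and os.path.isfile(os.path.join(directory, f))
    )
    datasets = []
    for p in paths:
        try:
            datasets.append((p, pydicom.dcmread(p)))
        except Exception:  # not a DICOM file; skip silently
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory!r}")

    def sort_key(item):
        _, ds = item
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None and len(pos) == 3:
            return (0, float(pos[2]))
        return (1, float(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)

    arrays, ids = [], []
    shapes = {}
    for p, ds in datasets:
        arr = ds.pixel_array.astype(float)
        if arr.ndim != 2:
            raise ValueError(f"{p}: expected a single-frame grayscale image, got shape {arr.shape}")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
        ids.append(str(getattr(ds, "SOPInstanceUID", os.path.basename(p))))
        shapes.setdefault(arr.shape, []).append(p)
    if len(shapes) > 1:
        raise ValueError(f"mixed slice shapes in series: {shapes}")

    first = datasets[0][1]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("missing DICOM tag PixelSpacing (0028,0030)")
    spacing = tuple(float(v) for v in first.PixelSpacing)
    thickness = float(getattr(first, "SliceThickness", 0.0) or 0.0)
    separation = float(getattr(first, "SpacingBetweenSlices", 0.0) or 0.0)
    if separation == 0.0 and len(datasets) > 1:
        positions = [sort_key(d)[1] for d in datasets]
        separation = float(np.median(np.diff(positions))) if len(positions) > 1 else thickness
    if separation == 0.0:
        separation = thickness or 1.0

    stack = np.stack(arrays)
    lo, hi = stack.min(), stack.max()
    stack = np.zeros_like(stack) if hi == lo else (stack - lo) / (hi - lo)
    return MRSeries(
        slices=list(stack),
        pixel_spacing=spacing,
        slice_thickness=thickness,
        slice_separation=separation,
        ids=ids,
    )


_MAX_CODE = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}


def read_raster(path: str | os.PathLike) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG/PGM/TIFF raster and scale into [0, 1]."""
    arr = iio.imread(os.fspath(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: color or multi-channel input is not supported (shape {arr.shape})")
    if arr.dtype not in _MAX_CODE:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16")
    return arr.astype(float) / _MAX_CODE[arr.dtype]


def write_raster(path: str | os.PathLike, image: np.ndarray, bits: int = 16) -> None:
    """Write a [0, 1] raster as an 8- or 16-bit grayscale PNG/PGM/TIFF."""
    image = np.clip(as_float_image(image), 0.0, 1.0)
    if bits == 16:
        iio.imwrite(os.fspath(path), np.round(image * 65535).astype(np.uint16))
    elif bits == 8:
        iio.imwrite(os.fspath(path), np.round(image * 255).astype(np.uint8))
    else:
        raise ValueError("bits must be 8 or 16")


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask stored as an 8-bit {0, 255} PNG."""
    arr = iio.imread(os.fspath(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: masks must be single-channel")
    return arr > (arr.max() / 2 if arr.max() > 1 else 0)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    iio.imwrite(os.fspath(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def write_sidecar(path: str | os.PathLike, metadata: dict) -> None:
    """Write structured-text metadata (pixel spacing etc.) next to a raster."""
    with open(os.fspath(path), "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)


def read_sidecar(path: str | os.PathLike) -> dict:
    with open(os.fspath(path)) as fh:
        return yaml.safe_load(fh)


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Min-max normalise an image to [0, 1]; a constant image maps to zeros."""
    image = as_float_image(image)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)
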