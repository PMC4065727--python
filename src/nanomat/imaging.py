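"""Micrograph I/O and intensity histograms.

Scanning-electron micrographs of fibrous mats are read into a canonical
8-bit grayscale representation.  All depth-profile analysis downstream is
driven by the *differential intensity histogram* t(g): the pixel count at
each of the 256 gray levels, together with its occupied range [a, b]
(infimum/supremum), mean mu and population standard deviation sigma.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GrayscaleImage",
    "IntensityHistogram",
    "load_grayscale",
    "intensity_histogram",
    "save_png",
    "write_histogram_csv",
]

#: ITU-R BT.601 luminance weights used to collapse RGB to gray.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayscaleImage:
    """An 8-bit grayscale raster.

    Pixels are stored row-major with the origin at the top-left corner;
    geometric measurements downstream refer to pixel *centers* at integer
    coordinates.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayscaleImage requires a non-empty 2D pixel grid")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensity levels must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class IntensityHistogram:
    """Differential histogram of a grayscale image.

    ``counts[g]`` is the number of pixels at level ``g``; ``a`` and ``b``
    are the lowest and highest occupied levels (infimum and supremum of the
    differential histogram); ``mu``/``sigma`` are the intensity mean and
    population standard deviation.
    """

    counts: np.ndarray
    total: int
    a: int
    b: int
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,) or counts.min() < 0:
            raise ValueError("counts must be 256 nonnegative integers")
        if int(counts.sum()) != self.total or self.total < 1:
            raise ValueError("histogram total inconsistent with counts")
        object.__setattr__(self, "counts", counts)


def load_grayscale(path: str | Path) -> GrayscaleImage:
    """Read a PNG or TIFF raster and convert it to canonical 8-bit grayscale.

    Color inputs are collapsed by the standard luminance weighting
    0.299 R + 0.587 G + 0.114 B (rounded half-up); 16-bit inputs are
    rescaled linearly by their own min/max onto [0, 255].
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff"}:
            import tifffile

            arr = np.asarray(tifffile.imread(str(path)))
        else:
            from PIL import Image

            with Image.open(path) as im:
                if im.mode in {"P", "LA", "RGBA"}:
                    im = im.convert("RGB" if im.mode in {"P", "RGBA"} else "L")
                arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - exercised via bad files
        raise ValueError(f"could not read raster image {path!s}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-area image: {path!s}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count in {path!s}: {arr.shape}")
        arr = np.floor(arr.astype(np.float64) @ _LUMA + 0.5)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported raster layout in {path!s}: shape {arr.shape}")
    arr = np.asarray(arr)
    if arr.dtype == np.uint8 or (arr.min() >= 0 and arr.max() <= 255):
        px = arr.astype(np.uint8)
    else:
        lo, hi = float(arr.min()), float(arr.max())
        if hi == lo:
            px = np.zeros(arr.shape, dtype=np.uint8)
        else:
            px = np.floor((arr.astype(np.float64) - lo) / (hi - lo) * 255 + 0.5)
            px = px.astype(np.uint8)
    return GrayscaleImage(pixels=px, source_id=path.stem)


def save_png(img: GrayscaleImage, path: str | Path) -> Path:
    """Write the image losslessly to an 8-bit grayscale PNG."""
    from PIL import Image

    path = Path(path)
    Image.fromarray(img.pixels, mode="L").save(path)
    return path


def intensity_histogram(img: GrayscaleImage) -> IntensityHistogram:
    """Differential intensity histogram with a, b, mu and sigma.

    sigma follows the population (divide-by-N) convention so that the
    mu +/- k*sigma layer thresholds are deterministic functions of the image.
    """
    counts = np.bincount(img.pixels.ravel(), minlength=256).astype(np.int64)
    occupied = np.flatnonzero(counts)
    a, b = int(occupied[0]), int(occupied[-1])
    total = int(counts.sum())
    levels = np.arange(256, dtype=np.float64)
    mu = float((counts * levels).sum() / total)
    sigma = float(np.sqrt((counts * (levels - mu) ** 2).sum() / total))
    return IntensityHistogram(counts=counts, total=total, a=a, b=b, mu=mu, sigma=sigma)


def write_histogram_csv(hist: IntensityHistogram, path: str | Path) -> Path:
    """Write the histogram as a two-column (level, count) CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["level", "count"])
        for level, count in enumerate(hist.counts):
            writer.writerow([level, int(count)])
    return path
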