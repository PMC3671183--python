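"""Image container and I/O for colorimetric RISH micrographs.

The analysis operates on single-channel intensity grids in which *stronger
hybridization signal means larger values*.  Brightfield chromogenic images
(dark stain on light background) must therefore be inverted exactly once
before any line scan is extracted; :class:`RishImage` tracks that state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile

#: Rec.709 luma weights used to collapse RGB micrographs to one channel.
REC709_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class RishImage:
    """A 2-D intensity grid with physical pixel size and inversion state.

    Parameters
    ----------
    pixels
        2-D array, integer (8/16-bit) or floating point in ``[0, 1]``.
        Row 0 is the apical edge of the section by convention.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    inverted
        Whether :func:`invert_image` has been applied (exactly once).
    source_id
        Opaque identity, e.g. ``(animal, image)``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    inverted: bool = False
    source_id: Any = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D grid")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _to_luminance(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to scalar luminance (Rec.709 weights)."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        return rgb @ np.asarray(REC709_WEIGHTS)
    raise ValueError(f"unsupported image shape {arr.shape}")


def read_image(path: str | Path, pixel_size_um: float, source_id: Any = None) -> RishImage:
    """Read a TIFF or PNG micrograph into a :class:`RishImage`.

    Grayscale images keep their native dtype; RGB images are converted to
    floating-point luminance on the native intensity scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.dtype not in (np.uint8, np.uint16) and not np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")
    return RishImage(_to_luminance(arr), pixel_size_um, inverted=False, source_id=source_id)


def write_image(img: RishImage | np.ndarray, path: str | Path, dtype: str = "uint16") -> None:
    """Write an image as single-channel TIFF or PNG.

    Floating-point data in ``[0, 1]`` is scaled to the full integer range.
    """
    arr = img.pixels if isinstance(img, RishImage) else np.asarray(img)
    if np.issubdtype(arr.dtype, np.floating):
        dt = np.dtype(dtype)
        arr = np.round(np.clip(arr, 0.0, 1.0) * np.iinfo(dt).max).astype(dt)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def invert_image(img: RishImage) -> RishImage:
    """Invert intensities so stain signal becomes bright.

    Integer images map ``v -> dtype_max - v``; floating-point images map
    ``v -> 1 - v``.  Applying the operation to an already-inverted image is
    an error (tracked by ``img.inverted``); inversion is an involution, so a
    double application would silently restore brightfield polarity.
    """
    if img.inverted:
        raise ValueError("image is already inverted")
    px = img.pixels
    if np.issubdtype(px.dtype, np.integer):
        out = np.iinfo(px.dtype).max - px
    else:
        out = 1.0 - px
    return replace(img, pixels=out, inverted=True)
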