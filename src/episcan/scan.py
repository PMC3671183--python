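"""Line-intensity scans perpendicular to the basal lamina.

The depth axis of a layered epithelium is defined per scan: a straight
segment anchored on the traced basal lamina, oriented perpendicular to the
local lamina tangent, running apically.  Intensity is sampled along the
segment by bilinear interpolation; the resulting profile runs apical -> basal
so that after normalization depth 0 is the apical end and depth 1 the lamina.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .image import RishImage

PERP_TOL = 1e-6


@dataclass(frozen=True)
class LaminaTrace:
    """Ordered polyline of (row, col) pixel coordinates tracing the basal lamina."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("trace needs >= 2 (row, col) points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive trace points must be distinct")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LaminaTrace":
        df = pd.read_csv(path)
        return cls(df[["row", "col"]].to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["row", "col"]).to_csv(path, index=False)


class ScanMeta(NamedTuple):
    animal_id: str
    image_id: str
    scan_id: str
    probe: str


@dataclass(frozen=True)
class ScanLine:
    """One scan segment: basal anchor, apically pointing unit direction, length."""

    basal_anchor: tuple[float, float]
    direction: tuple[float, float]  # unit vector in (row, col) pixel coords
    length_um: float
    step_um: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(float(np.hypot(*d)) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.length_um <= 0 or self.step_um <= 0:
            raise ValueError("length_um and step_um must be positive")


@dataclass(frozen=True)
class IntensityProfile:
    """Intensity vs. position along one scan, apical end first."""

    x: np.ndarray
    y: np.ndarray
    normalized: bool
    meta: ScanMeta
    n_points: int = field(init=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if len(x) != len(y) or len(x) < 2:
            raise ValueError("x and y must have equal length >= 2")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n_points", len(x))


def local_tangent(trace: LaminaTrace, anchor_index: int) -> np.ndarray:
    """Unit tangent of the lamina polyline at a vertex.

    Central difference over neighbouring vertices; one-sided difference at the
    endpoints.
    """
    pts = trace.points
    n = len(pts)
    if not 0 <= anchor_index < n:
        raise IndexError(f"anchor_index {anchor_index} out of range [0, {n})")
    lo = max(anchor_index - 1, 0)
    hi = min(anchor_index + 1, n - 1)
    d = pts[hi] - pts[lo]
    norm = float(np.hypot(*d))
    if norm == 0:
        raise ValueError("degenerate tangent (coincident neighbours)")
    return d / norm


def perpendicular_direction(trace: LaminaTrace, anchor_index: int) -> np.ndarray:
    """Unit vector perpendicular to the local lamina tangent, pointing apically.

    Apical is toward row 0, so of the two perpendiculars the one with negative
    row component is returned.  Exactly horizontal perpendiculars (vertical
    lamina) are rejected: no apical orientation exists.
    """
    t = local_tangent(trace, anchor_index)
    p = np.array([-t[1], t[0]])
    if abs(p[0]) < PERP_TOL:
        raise ValueError("lamina tangent is vertical; no apical perpendicular")
    if p[0] > 0:
        p = -p
    return p


def make_scan_line(
    trace: LaminaTrace,
    anchor_index: int,
    length_um: float,
    pixel_size_um: float,
    step_um: float | None = None,
) -> ScanLine:
    """Build a perpendicular scan of explicit length anchored at a trace vertex."""
    anchor = tuple(trace.points[anchor_index])
    direction = perpendicular_direction(trace, anchor_index)
    if step_um is None:
        step_um = pixel_size_um  # 1-pixel sampling step
    return ScanLine(anchor, tuple(direction), float(length_um), float(step_um))


def length_to_apical_edge(trace: LaminaTrace, anchor_index: int, pixel_size_um: float) -> float:
    """Distance (um) from a basal anchor to image row 0 along the perpendicular.

    Useful for synthetic images where the apical surface is exactly row 0; for
    real micrographs supply an explicit scan length instead.
    """
    anchor = trace.points[anchor_index]
    direction = perpendicular_direction(trace, anchor_index)
    # anchor_row + t * dir_row = 0  (dir_row < 0 by construction)
    t_px = anchor[0] / -direction[0]
    return float(t_px * pixel_size_um)


def extract_scan(img: RishImage, scan: ScanLine, meta: ScanMeta) -> IntensityProfile:
    """Sample a raw intensity profile along a scan line.

    Bilinear interpolation at positions ``0, step, ..., length`` (um) measured
    from the apical end of the segment; the basal anchor is the last sample.
    The image must be inverted (signal-bright) first.
    """
    if not img.inverted:
        raise ValueError("image must be inverted before scanning")
    x_um = np.arange(0.0, scan.length_um, scan.step_um)
    if scan.length_um - x_um[-1] > 1e-6 * scan.step_um:
        x_um = np.append(x_um, scan.length_um)  # basal anchor is always sampled
    else:
        x_um[-1] = scan.length_um
    anchor = np.asarray(scan.basal_anchor, dtype=float)
    direction = np.asarray(scan.direction, dtype=float)
    apical_start = anchor + direction * (scan.length_um / img.pixel_size_um)
    # positions run apical -> basal
    coords = apical_start[:, None] - direction[:, None] * (x_um / img.pixel_size_um)
    h, w = img.shape
    if (
        coords[0].min() < -1e-9
        or coords[0].max() > h - 1 + 1e-9
        or coords[1].min() < -1e-9
        or coords[1].max() > w - 1 + 1e-9
    ):
        raise ValueError("scan line exits image bounds")
    y = map_coordinates(img.pixels.astype(np.float64), coords, order=1, mode="nearest")
    return IntensityProfile(x=x_um, y=y, normalized=False, meta=meta)


def profiles_to_frame(profiles: list[IntensityProfile]) -> pd.DataFrame:
    """Serialize raw profiles to the interchange table (one row per sample)."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "probe": p.meta.probe,
                    "animal_id": p.meta.animal_id,
                    "image_id": p.meta.image_id,
                    "scan_id": p.meta.scan_id,
                    "x_um": p.x,
                    "intensity": p.y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_profiles(df: pd.DataFrame) -> list[IntensityProfile]:
    """Inverse of :func:`profiles_to_frame`."""
    out = []
    keys = ["probe", "animal_id", "image_id", "scan_id"]
    for (probe, animal, image, scan_id), g in df.groupby(keys, sort=False):
        g = g.sort_values("x_um")
        meta = ScanMeta(str(animal), str(image), str(scan_id), str(probe))
        out.append(
            IntensityProfile(
                x=g["x_um"].to_numpy(), y=g["intensity"].to_numpy(), normalized=False, meta=meta
            )
        )
    return out
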