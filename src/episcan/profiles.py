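"""Normalization and hierarchical averaging of line-scan profiles.

Each raw scan is normalized to its own maxima (depth to the scan length, so
the basal lamina sits at x = 1; intensity to the profile peak).  Scans are
then averaged per animal on a fixed 500-point grid by linear interpolation,
each animal curve is renormalized to peak 1, and animal curves are averaged
across the cohort on a 100-point grid with a per-point SEM whose denominator
is the number of animals.  The group curve is *not* renormalized again, so
its peak may sit slightly below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scan import IntensityProfile


@dataclass(frozen=True)
class AveragingConfig:
    n_points_animal: int = 500
    n_points_group: int = 100
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.n_points_animal < 2 or self.n_points_group < 2:
            raise ValueError("point counts must be >= 2")
        if self.n_points_group > self.n_points_animal:
            raise ValueError("n_points_group must be <= n_points_animal")
        if self.interpolation != "linear":
            raise ValueError("only linear interpolation is supported")


@dataclass(frozen=True)
class AveragedProfile:
    """Mean curve on a uniform [0, 1] grid with per-point SEM and provenance."""

    x_grid: np.ndarray
    mean: np.ndarray
    sem: np.ndarray | None
    n_contributing: int
    level: str  # "animal" | "group"
    probe: str

    def __post_init__(self) -> None:
        x = np.asarray(self.x_grid, dtype=float)
        m = np.asarray(self.mean, dtype=float)
        if len(x) != len(m):
            raise ValueError("x_grid and mean length mismatch")
        if self.sem is not None:
            s = np.asarray(self.sem, dtype=float)
            if len(s) != len(x):
                raise ValueError("sem length mismatch")
            if np.any(s < 0):
                raise ValueError("sem must be nonnegative")
            object.__setattr__(self, "sem", s)
        if self.n_contributing < 1:
            raise ValueError("n_contributing must be >= 1")
        if self.level not in ("animal", "group"):
            raise ValueError("level must be 'animal' or 'group'")
        object.__setattr__(self, "x_grid", x)
        object.__setattr__(self, "mean", m)


def uniform_grid(n_points: int) -> np.ndarray:
    """Uniform grid on [0, 1], endpoints included, spacing 1/(n-1)."""
    return np.linspace(0.0, 1.0, n_points)


class ZeroProfileError(ValueError):
    """Raised for an all-zero intensity profile, which cannot be normalized."""


def normalize_profile(p: IntensityProfile) -> IntensityProfile:
    """Normalize depth and intensity each to their profile maximum.

    After normalization ``x`` spans [0, 1] with 1 at the basal lamina and
    ``max(y) == 1`` exactly.
    """
    if p.normalized:
        raise ValueError("profile is already normalized")
    ymax = float(np.max(p.y))
    if ymax <= 0:
        raise ZeroProfileError(
            f"all-zero intensity profile {p.meta}; excluded from averaging"
        )
    return replace(p, x=p.x / float(np.max(p.x)), y=p.y / ymax, normalized=True)


def average_profiles(
    profiles: Sequence[IntensityProfile],
    n_points: int,
    interpolation: str = "linear",
    level: str = "animal",
) -> AveragedProfile:
    """Pointwise mean of normalized profiles resampled to a common grid.

    Every profile is linearly interpolated onto the uniform ``n_points`` grid
    on [0, 1]; the mean is arithmetic and no SEM is attached at this level.
    """
    if interpolation != "linear":
        raise ValueError("only linear interpolation is supported")
    if len(profiles) == 0:
        raise ValueError("no profiles to average")
    probes = {p.meta.probe for p in profiles}
    if len(probes) != 1:
        raise ValueError(f"mixed probes in one average: {sorted(probes)}")
    if any(not p.normalized for p in profiles):
        raise ValueError("all profiles must be normalized before averaging")
    grid = uniform_grid(n_points)
    stack = np.vstack([np.interp(grid, p.x, p.y) for p in profiles])
    return AveragedProfile(
        x_grid=grid,
        mean=stack.mean(axis=0),
        sem=None,
        n_contributing=len(profiles),
        level=level,
        probe=probes.pop(),
    )


def renormalize(curve: AveragedProfile) -> AveragedProfile:
    """Rescale a mean curve so its peak is exactly 1."""
    peak = float(np.max(curve.mean))
    if peak <= 0:
        raise ZeroProfileError("cannot renormalize an all-zero averaged curve")
    sem = None if curve.sem is None else curve.sem / peak
    return replace(curve, mean=curve.mean / peak, sem=sem)


def hierarchical_average(
    profiles_by_animal: Mapping[str, Sequence[IntensityProfile]],
    cfg: AveragingConfig = AveragingConfig(),
) -> AveragedProfile:
    """Two-level average: scans -> animal curve (renormalized) -> group curve.

    Per animal the scans are averaged on the ``n_points_animal`` grid and the
    animal curve is renormalized to peak 1.  Animal curves are then resampled
    onto the coarser ``n_points_group`` grid and averaged; the per-point SEM
    uses the number of animals as denominator (0 when there is one animal).
    """
    if len(profiles_by_animal) == 0:
        raise ValueError("no animals")
    animal_curves = []
    probe = None
    for animal in profiles_by_animal:
        curve = renormalize(average_profiles(profiles_by_animal[animal], cfg.n_points_animal))
        probe = curve.probe
        animal_curves.append(curve)
    grid = uniform_grid(cfg.n_points_group)
    stack = np.vstack([np.interp(grid, c.x_grid, c.mean) for c in animal_curves])
    n = len(animal_curves)
    if n > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        warnings.warn("single animal: SEM reported as 0", stacklevel=2)
        sem = np.zeros(len(grid))
    return AveragedProfile(
        x_grid=grid,
        mean=stack.mean(axis=0),
        sem=sem,
        n_contributing=n,
        level="group",
        probe=probe,  # type: ignore[arg-type]
    )


def curves_to_frame(curves: Iterable[AveragedProfile]) -> pd.DataFrame:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "probe": c.probe,
                    "level": c.level,
                    "x": c.x_grid,
                    "mean": c.mean,
                    "sem": c.sem if c.sem is not None else np.nan,
                    "n": c.n_contributing,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_curves(df: pd.DataFrame) -> dict[str, AveragedProfile]:
    """Read group-level curves back from the interchange table, keyed by probe."""
    out: dict[str, AveragedProfile] = {}
    for (probe, level), g in df.groupby(["probe", "level"], sort=False):
        g = g.sort_values("x")
        sem = g["sem"].to_numpy()
        out[str(probe)] = AveragedProfile(
            x_grid=g["x"].to_numpy(),
            mean=g["mean"].to_numpy(),
            sem=None if np.all(np.isnan(sem)) else sem,
            n_contributing=int(g["n"].iloc[0]),
            level=str(level),
            probe=str(probe),
        )
    return out


def plot_curves(curves: Iterable[AveragedProfile], ax=None, window=None):
    """Plot group curves with SEM bands; optionally shade a marker window.

    Requires matplotlib (the ``plot`` extra).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        (line,) = ax.plot(c.x_grid, c.mean, label=f"{c.probe} (n={c.n_contributing})")
        if c.sem is not None:
            ax.fill_between(c.x_grid, c.mean - c.sem, c.mean + c.sem,
                            alpha=0.25, color=line.get_color(), linewidth=0)
    if window is not None:
        ax.axvspan(window.x1, window.x2, color="0.85", zorder=0)
    ax.set_xlabel("normalized epithelial depth (0 = apical, 1 = basal lamina)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    return ax


def save_curves(curves: Iterable[AveragedProfile], path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def load_curves(path: str | Path) -> dict[str, AveragedProfile]:
    return frame_to_curves(pd.read_csv(path))
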