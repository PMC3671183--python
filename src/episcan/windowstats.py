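"""Marker-window area integrals and distribution comparison.

A marker window is a depth interval [x1, x2] of the normalized epithelium,
typically the band occupied by a marker of immature neurons (GAP43); the
defaults (0.63, 0.93) place it basally.  Windowed area integrals of the
normalized group curves quantify how much of each probe's signal falls in
the band, and a two-sample Kolmogorov–Smirnov statistic compares two probes'
signal distributions restricted to the band.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .profiles import AveragedProfile

#: The default marker window: the basal band of the immature-neuron marker.
DEFAULT_WINDOW_X1 = 0.63
DEFAULT_WINDOW_X2 = 0.93


@dataclass(frozen=True)
class MarkerWindow:
    x1: float = DEFAULT_WINDOW_X1
    x2: float = DEFAULT_WINDOW_X2
    source: str = "explicit"  # "explicit" | "half_max_of_marker"
    marker_probe: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.x1 < self.x2 <= 1.0):
            raise ValueError(f"require 0 <= x1 < x2 <= 1, got ({self.x1}, {self.x2})")

    @property
    def width(self) -> float:
        return self.x2 - self.x1


@dataclass(frozen=True)
class AreaIntegral:
    probe: str
    window: MarkerWindow
    value: float


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    n1: int
    n2: int
    mode: str
    #: what the n's count — grid points of the averaged curves, not scans
    sample_unit: str = "grid_points"
    p_is_placeholder: bool = False


def _window_restriction(curve: AveragedProfile, window: MarkerWindow):
    """Grid and values inside [x1, x2] with interpolated values at both edges."""
    x, y = curve.x_grid, curve.mean
    if window.x1 < x[0] - 1e-12 or window.x2 > x[-1] + 1e-12:
        raise ValueError("window outside curve grid span")
    inner = (x > window.x1) & (x < window.x2)
    xs = np.concatenate(([window.x1], x[inner], [window.x2]))
    ys = np.concatenate(
        ([np.interp(window.x1, x, y)], y[inner], [np.interp(window.x2, x, y)])
    )
    return xs, ys


def area_integral(curve: AveragedProfile, window: MarkerWindow) -> AreaIntegral:
    """Trapezoidal integral of a mean curve over the window.

    The curve is evaluated exactly at x1 and x2 by linear interpolation and
    those points are inserted as integration endpoints, so the result has no
    grid-truncation bias.
    """
    xs, ys = _window_restriction(curve, window)
    return AreaIntegral(curve.probe, window, float(np.trapezoid(ys, xs)))


def derive_window(marker: AveragedProfile, rule: str = "half_max") -> MarkerWindow:
    """Derive the window from a marker curve as its half-maximum band.

    Requires a single contiguous region above half max; the window endpoints
    are the outer half-max crossings (linear interpolation between grid
    points).
    """
    if rule != "half_max":
        raise ValueError(f"unknown rule {rule!r}")
    x, y = marker.x_grid, marker.mean
    half = float(np.max(y)) / 2.0
    above = y > half
    if not above.any():
        raise ValueError("marker curve never exceeds half max")
    if above.all():
        raise ValueError("marker curve never crosses half max (constant-like curve)")
    # number of contiguous supra-half-max runs
    n_runs = (np.diff(np.concatenate(([0], above.astype(int), [0]))) == 1).sum()
    if n_runs != 1:
        raise ValueError(
            f"{n_runs} disjoint supra-half-max regions; supply an explicit window"
        )
    i0, i1 = np.flatnonzero(above)[[0, -1]]
    if i0 == 0:
        x1 = x[0]
    else:
        x1 = x[i0 - 1] + (half - y[i0 - 1]) / (y[i0] - y[i0 - 1]) * (x[i0] - x[i0 - 1])
    if i1 == len(x) - 1:
        x2 = x[-1]
    else:
        x2 = x[i1] + (half - y[i1]) / (y[i1 + 1] - y[i1]) * (x[i1 + 1] - x[i1])
    return MarkerWindow(float(x1), float(x2), source="half_max_of_marker", marker_probe=marker.probe)


def ks_compare(
    a: AveragedProfile,
    b: AveragedProfile,
    window: MarkerWindow,
    mode: str = "pointwise_values",
) -> KSResult:
    """Two-sample KS comparison of two probe distributions within the window.

    ``pointwise_values`` (the evident published procedure) treats the two
    curves' values at grid points inside the window as the two samples:
    D = sup |ECDF1 - ECDF2| with the asymptotic Kolmogorov p-value at
    effective n = n1*n2/(n1+n2).  ``density_cdf`` instead treats each curve
    inside the window as an unnormalized density over depth and reports the
    sup-norm distance between the two normalized cumulative integrals; no
    p-value is defined there (reported as 1 with a flag).
    """
    in_a = (a.x_grid >= window.x1) & (a.x_grid <= window.x2)
    in_b = (b.x_grid >= window.x1) & (b.x_grid <= window.x2)
    va, vb = a.mean[in_a], b.mean[in_b]
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("window restriction is empty")
    if mode == "pointwise_values":
        d = float(stats.ks_2samp(va, vb, method="asymp").statistic)
        ne = len(va) * len(vb) / (len(va) + len(vb))
        p = float(special.kolmogorov(math.sqrt(ne) * d))
        return KSResult(D=d, p_value=min(max(p, 0.0), 1.0), n1=len(va), n2=len(vb), mode=mode)
    if mode == "density_cdf":
        xa, ya = _window_restriction(a, window)
        xb, yb = _window_restriction(b, window)
        ia = _cumtrapz_normalized(xa, ya)
        ib = _cumtrapz_normalized(xb, yb)
        xs = np.union1d(xa, xb)
        d = float(np.max(np.abs(np.interp(xs, xa, ia) - np.interp(xs, xb, ib))))
        return KSResult(
            D=d, p_value=1.0, n1=len(xa), n2=len(xb), mode=mode,
            sample_unit="depth_cdf", p_is_placeholder=True,
        )
    raise ValueError(f"unknown mode {mode!r}")


def _cumtrapz_normalized(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(np.diff(x) * (y[1:] + y[:-1]) / 2.0)))
    total = c[-1]
    if total <= 0:
        raise ValueError("all-zero curve in window; density CDF undefined")
    return c / total


def ks_exact_p(sample1: np.ndarray, sample2: np.ndarray) -> float:
    """Exact two-sample KS p-value by enumerating all label assignments.

    Conditional permutation null on the pooled values; feasible for
    n1 + n2 <= 20.  Ties are handled by the same ECDF convention as the
    statistic itself.
    """
    v1 = np.asarray(sample1, dtype=float)
    v2 = np.asarray(sample2, dtype=float)
    n1, n2 = len(v1), len(v2)
    if n1 > 10 or n2 > 10:
        raise ValueError("exact p restricted to n1, n2 <= 10")
    pooled = np.concatenate([v1, v2])
    d_obs = float(stats.ks_2samp(v1, v2).statistic)
    total = math.comb(n1 + n2, n1)
    count = 0
    idx = range(n1 + n2)
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(comb)] = True
        d = float(stats.ks_2samp(pooled[mask], pooled[~mask]).statistic)
        if d >= d_obs - 1e-12:
            count += 1
    return count / total


def compare_windowed_integrals(
    curves: Mapping[str, AveragedProfile], window: MarkerWindow
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Area integrals per probe and all pairwise ratios over one window.

    Returns ``(integrals, ratios)`` tables; ratios cover ordered pairs of
    distinct probes.
    """
    if len(curves) < 2:
        raise ValueError("need at least two probes to compare")
    integrals = pd.DataFrame(
        {
            "probe": list(curves),
            "x1": window.x1,
            "x2": window.x2,
            "integral": [area_integral(c, window).value for c in curves.values()],
        }
    )
    vals = dict(zip(integrals["probe"], integrals["integral"]))
    rows = [
        {"probe_num": p, "probe_den": q, "ratio": vals[p] / vals[q]}
        for p, q in itertools.permutations(vals, 2)
    ]
    return integrals, pd.DataFrame(rows)
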