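"""Seeded ground-truth generators: layered-epithelium images and Ct tables.

The image generator emulates a coronal section of a layered sensory
epithelium photographed in brightfield: the apical surface lies at image row
0, the basal lamina follows a sinusoid below it, and between the two the
depth axis (0 apical, 1 at the lamina) is split into named layers.  A probe
occupies a subset of layers with configured intensity; signal is rendered
either as uniform layer fill (continuous mode, exact analytic oracle) or as
cell-body blobs (Gaussian-profile discs at Poisson-distributed centers,
combined by pointwise maximum because chromogenic stain saturates).  The Ct
generator produces qPCR tables with a reference gene and designed fold
changes.

Every generator call is driven by one explicit integer seed, so identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .image import RishImage
from .qpcr import CtTable
from .scan import LaminaTrace

DEFAULT_PIXEL_SIZE_UM = 0.372


@dataclass(frozen=True)
class EpitheliumModel:
    """Parametric description of the synthetic epithelium and its probes.

    ``layer_boundaries`` are strictly increasing depth fractions in (0, 1)
    splitting [0, 1] into ``len(layer_boundaries) + 1`` layers (apical
    first); each probe assigns one mean intensity in [0, 1] per layer.
    """

    image_height_px: int = 2048
    image_width_px: int = 2048
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    lamina_baseline_px: float = 160.0
    lamina_amplitude_px: float = 8.0
    lamina_wavelength_px: float = 1024.0
    layer_boundaries: tuple[float, ...] = (0.25, 0.63, 0.93)
    layer_names: tuple[str, ...] = ("sus", "mOSN", "iOSN", "basal")
    probe_profiles: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {"probe": (0.0, 0.85, 0.85, 0.0)}
    )
    blob_density_per_um2: float = 0.0
    blob_radius_um: float = 1.6
    background_level: float = 0.08
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0 or self.lamina_wavelength_px <= 0:
            raise ValueError("pixel size and lamina wavelength must be positive")
        if self.lamina_amplitude_px < 0 or self.blob_density_per_um2 < 0:
            raise ValueError("amplitude and blob density must be nonnegative")
        if self.blob_radius_um <= 0:
            raise ValueError("blob radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        b = np.asarray(self.layer_boundaries, dtype=float)
        if np.any(b <= 0) or np.any(b >= 1) or np.any(np.diff(b) <= 0):
            raise ValueError("layer_boundaries must be strictly increasing in (0, 1)")
        n_layers = len(b) + 1
        if len(self.layer_names) != n_layers:
            raise ValueError("layer_names must name every layer")
        positive = []
        for probe, prof in self.probe_profiles.items():
            if len(prof) != n_layers:
                raise ValueError(f"probe {probe!r} must assign an intensity per layer")
            if any(not 0.0 <= v <= 1.0 for v in prof):
                raise ValueError(f"probe {probe!r} intensities must be in [0, 1]")
            positive += [v for v in prof if v > 0]
        if not 0.0 <= self.background_level < 1.0:
            raise ValueError("background_level must be in [0, 1)")
        if positive and self.background_level >= min(positive):
            raise ValueError("background must stay below the weakest positive layer signal")
        if self.lamina_baseline_px + self.lamina_amplitude_px >= self.image_height_px:
            raise ValueError("lamina exits the image")

    def lamina_row(self, col: np.ndarray | float) -> np.ndarray | float:
        """Basal-lamina row as a function of column (sinusoidal)."""
        return self.lamina_baseline_px + self.lamina_amplitude_px * np.sin(
            2.0 * math.pi * np.asarray(col, dtype=float) / self.lamina_wavelength_px
        )

    @property
    def blob_coverage(self) -> float:
        """Expected within-layer fill fraction of the blob field.

        For Gaussian-profile discs (sigma = blob radius) at Poisson density
        lambda combined by maximum, the mean of the field at amplitude 1 is
        k / (k + 1) with k = 2*pi*lambda*sigma^2; 1.0 in continuous mode.
        """
        if self.blob_density_per_um2 == 0:
            return 1.0
        k = 2.0 * math.pi * self.blob_density_per_um2 * self.blob_radius_um**2
        return k / (k + 1.0)


def _disc_area_left_of(r: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Area of a disc of radius r (centered at u=0) with u < t."""
    t = np.clip(t, -r, r)
    with np.errstate(invalid="ignore"):
        out = np.pi * r**2 / 2.0 + t * np.sqrt(np.maximum(r**2 - t**2, 0.0)) \
            + r**2 * np.arcsin(np.where(r > 0, t / np.where(r > 0, r, 1.0), 0.0))
    return np.where(r > 0, out, 0.0)


def _strip_disc_area(r: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Area of a disc of radius r intersected with the strip a < u < b."""
    return _disc_area_left_of(r, b) - _disc_area_left_of(r, a)


def expected_blob_field(
    x_um: np.ndarray,
    bands_um: Sequence[tuple[float, float]],
    amplitude: float,
    density_per_um2: float,
    sigma_um: float,
    n_quad: int = 400,
) -> np.ndarray:
    """Exact expectation of the max-combined Gaussian blob field.

    ``x_um`` are depth positions; ``bands_um`` the depth intervals seeded
    with blobs of common ``amplitude``.  For a Poisson process of rate
    ``lambda`` per square micrometre with kernels ``A*exp(-d^2/(2*sigma^2))``
    combined by pointwise maximum, the exceedance probability at threshold
    ``t = A*exp(-s^2/2)`` is ``1 - exp(-lambda * area(sigma*s))`` where
    ``area`` is the disc-strip intersection at radius ``sigma*s``; the mean
    follows by integrating over thresholds.  Far inside a band this reduces
    to ``A*k/(k+1)`` with ``k = 2*pi*lambda*sigma^2``.
    """
    x_um = np.atleast_1d(np.asarray(x_um, dtype=float))
    s = np.linspace(1e-6, 6.0, n_quad)
    r = sigma_um * s  # (s,)
    area = np.zeros((len(x_um), n_quad))
    for lo, hi in bands_um:
        area += _strip_disc_area(r[None, :], (lo - x_um)[:, None], (hi - x_um)[:, None])
    integrand = (1.0 - np.exp(-density_per_um2 * area)) * amplitude * s * np.exp(-s**2 / 2.0)
    return np.trapezoid(integrand, s, axis=1)


@dataclass(frozen=True)
class GroundTruth:
    """Oracle for one generated image: geometry plus expected profiles."""

    lamina_trace: LaminaTrace
    layer_boundaries: tuple[float, ...]
    layer_intensities: tuple[float, ...]
    background: float
    coverage: float
    probe: str
    depth_um: float = 0.0
    blob_density_per_um2: float = 0.0
    blob_sigma_um: float = 1.0

    def layer_index(self, x: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.layer_boundaries), x, side="right")

    def design_profile(self, x: np.ndarray) -> np.ndarray:
        """Noiseless continuous-mode pixel value at normalized depth x in [0, 1]."""
        x = np.asarray(x, dtype=float)
        vals = self.background + np.asarray(self.layer_intensities)[self.layer_index(x)]
        return np.where((x >= 0) & (x <= 1), vals, self.background)

    def _signal_bands(self) -> tuple[list[tuple[float, float]], float]:
        edges = np.concatenate(([0.0], np.asarray(self.layer_boundaries), [1.0]))
        amps = np.asarray(self.layer_intensities)
        pos = amps > 0
        if pos.any() and len(set(amps[pos])) > 1:
            raise NotImplementedError(
                "exact blob expectation requires one common positive amplitude"
            )
        bands = [(edges[i], edges[i + 1]) for i in range(len(amps)) if pos[i]]
        amp = float(amps[pos][0]) if pos.any() else 0.0
        return bands, amp

    def expected_group_profile(self, x: np.ndarray) -> np.ndarray:
        """Expected normalized group-level curve at depth x in [0, 1].

        Continuous mode: the piecewise-constant design profile normalized by
        its peak.  Blob mode: the exact Boolean-model expectation of the
        max-combined blob field (including edge spread at layer boundaries),
        plus background, normalized by its peak — mirroring the pipeline's
        max-normalization of averaged curves.
        """
        x = np.asarray(x, dtype=float)
        if self.blob_density_per_um2 == 0:
            peak = self.background + max(self.layer_intensities)
            return self.design_profile(x) / peak
        bands, amp = self._signal_bands()
        bands_um = [(lo * self.depth_um, hi * self.depth_um) for lo, hi in bands]

        def raw(xx: np.ndarray) -> np.ndarray:
            return self.background + expected_blob_field(
                xx * self.depth_um, bands_um, amp,
                self.blob_density_per_um2, self.blob_sigma_um,
            )

        peak = float(raw(np.linspace(0.0, 1.0, 1001)).max())
        return raw(x) / peak


def _trace_from_model(model: EpitheliumModel, step_px: int = 4) -> LaminaTrace:
    cols = np.arange(0, model.image_width_px, step_px, dtype=float)
    if cols[-1] != model.image_width_px - 1:
        cols = np.append(cols, model.image_width_px - 1)
    return LaminaTrace(np.column_stack([model.lamina_row(cols), cols]))


def generate_epithelium_image(
    model: EpitheliumModel, probe: str, seed: int | None = None
) -> tuple[RishImage, GroundTruth]:
    """Render a signal-polarity image of one probe plus its ground truth.

    The returned image is *signal-bright* (stain = high values), i.e. already
    in the polarity the scanning stage expects, and is flagged ``inverted``.
    Use :func:`to_brightfield` to obtain the corresponding raw micrograph.
    """
    if probe not in model.probe_profiles:
        raise KeyError(f"unknown probe {probe!r}")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    h, w = model.image_height_px, model.image_width_px
    lamina = np.asarray(model.lamina_row(np.arange(w)))
    rows = np.arange(h, dtype=float)[:, None]
    depth = rows / lamina[None, :]  # normalized depth per pixel
    above = depth <= 1.0
    intensities = np.asarray(model.probe_profiles[probe], dtype=float)
    if model.blob_density_per_um2 > 0:
        signal = _render_blobs(model, intensities, lamina, above, rng)
    else:
        layer_idx = np.searchsorted(np.asarray(model.layer_boundaries), np.clip(depth, 0, 1),
                                    side="right")
        signal = np.where(above, intensities[layer_idx], 0.0)
    img = model.background_level + signal
    if model.noise_sd > 0:
        img = img + rng.normal(0.0, model.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = GroundTruth(
        lamina_trace=_trace_from_model(model),
        layer_boundaries=tuple(model.layer_boundaries),
        layer_intensities=tuple(intensities),
        background=model.background_level,
        coverage=model.blob_coverage,
        probe=probe,
        depth_um=model.lamina_baseline_px * model.pixel_size_um,
        blob_density_per_um2=model.blob_density_per_um2,
        blob_sigma_um=model.blob_radius_um,
    )
    return RishImage(img, model.pixel_size_um, inverted=True, source_id=probe), truth


def _render_blobs(
    model: EpitheliumModel,
    intensities: np.ndarray,
    lamina: np.ndarray,
    above: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max-combined Gaussian cell-body blobs, masked to the epithelium."""
    h, w = above.shape
    area_um2 = h * w * model.pixel_size_um**2
    n = rng.poisson(model.blob_density_per_um2 * area_um2)
    sigma_px = model.blob_radius_um / model.pixel_size_um
    r_ext = max(int(math.ceil(3.0 * sigma_px)), 1)
    yy, xx = np.ogrid[-r_ext : r_ext + 1, -r_ext : r_ext + 1]
    kernel = np.exp(-(yy**2 + xx**2) / (2.0 * sigma_px**2))
    field = np.zeros((h, w))
    if n > 0:
        crow = rng.integers(0, h, size=n)
        ccol = rng.integers(0, w, size=n)
        depth_c = crow / lamina[ccol]
        layer_idx = np.searchsorted(np.asarray(model.layer_boundaries),
                                    np.clip(depth_c, 0, 1), side="right")
        amp = np.where(depth_c <= 1.0, intensities[layer_idx], 0.0)
        keep = amp > 0
        for r, c, a in zip(crow[keep], ccol[keep], amp[keep]):
            r0, r1 = max(r - r_ext, 0), min(r + r_ext + 1, h)
            c0, c1 = max(c - r_ext, 0), min(c + r_ext + 1, w)
            kr0, kc0 = r0 - (r - r_ext), c0 - (c - r_ext)
            patch = field[r0:r1, c0:c1]
            np.maximum(patch, a * kernel[kr0 : kr0 + r1 - r0, kc0 : kc0 + c1 - c0], out=patch)
    return np.where(above, field, 0.0)


def to_brightfield(img: RishImage) -> RishImage:
    """Convert a signal-polarity image to its brightfield (stain-dark) form."""
    if not img.inverted:
        raise ValueError("image is already in brightfield polarity")
    return replace(img, pixels=1.0 - img.pixels, inverted=False)


# ---------------------------------------------------------------------------
# Study-mimicking presets


def _solve_designed_boundary(
    target_ratio: float,
    window: tuple[float, float],
    amp: float,
    background: float,
    density: float,
    sigma_um: float,
    depth_um: float,
    apical_edge: float = 0.25,
    basal_edge: float = 0.93,
) -> float:
    """Depth boundary m making the expected windowed-integral ratio exact.

    The full-neuron-layer probe occupies [apical_edge, basal_edge]; the
    restricted probe occupies [apical_edge, m].  The ratio of the two
    normalized expected group curves integrated over the window is solved
    for m by bisection; in continuous mode the expectation is the piecewise
    design profile, in blob mode the exact Boolean-model expectation
    (including boundary edge spread).
    """
    from scipy.optimize import brentq

    x1, x2 = window
    xs = np.linspace(x1, x2, 1201)

    def normalized_curve(bands: list[tuple[float, float]]) -> np.ndarray:
        if density == 0:
            vals = np.full_like(xs, background)
            for lo, hi in bands:
                vals = np.where((xs >= lo) & (xs <= hi), background + amp, vals)
            return vals / (background + amp)
        bands_um = [(lo * depth_um, hi * depth_um) for lo, hi in bands]
        dense = np.linspace(0.0, 1.0, 1001)
        raw_dense = background + expected_blob_field(
            dense * depth_um, bands_um, amp, density, sigma_um
        )
        raw = background + expected_blob_field(xs * depth_um, bands_um, amp, density, sigma_um)
        return raw / raw_dense.max()

    i_full = np.trapezoid(normalized_curve([(apical_edge, basal_edge)]), xs)

    def f(m: float) -> float:
        return i_full / np.trapezoid(normalized_curve([(apical_edge, m)]), xs) - target_ratio

    return float(brentq(f, x1 + 0.01, x2 - 0.01, xtol=1e-10))


def olfactory_cohort_model(
    target_ratio: float = 2.0,
    window: tuple[float, float] = (0.63, 0.93),
    blob_mode: bool = True,
    small: bool = False,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> EpitheliumModel:
    """Three-probe cohort model with a designed windowed-integral ratio.

    Probes: ``Gb1-like`` fills the whole neuron layer (0.25-0.93 of depth),
    ``Gg13-like`` only its upper portion, ``GAP43-like`` exactly the marker
    window.  The upper/lower neuron boundary ``m`` is solved numerically so
    that the expected windowed-integral ratio Gb1-like : Gg13-like of the
    normalized group curves equals ``target_ratio`` under the configured
    rendering mode (the blob-mode expectation includes the edge spread of
    the cell-body texture at layer boundaries).  ``small=True`` shrinks the
    canvas (not the epithelium depth or pixel size) for repeated simulation
    studies.
    """
    x1, x2 = window
    amp = 0.85
    background = 0.08
    density = 0.5 if blob_mode else 0.0
    sigma_um = 1.0
    depth_um = 160.0 * DEFAULT_PIXEL_SIZE_UM
    m = _solve_designed_boundary(
        target_ratio, window, amp, background, density, sigma_um, depth_um
    )
    if not x1 < m < x2:
        raise ValueError("designed boundary falls outside the window; adjust the design")
    boundaries = (0.25, x1, m, x2)
    names = ("sus", "mOSN-upper", "mOSN-lower", "iOSN", "basal")
    probes = {
        "Gb1-like": (0.0, amp, amp, amp, 0.0),
        "Gg13-like": (0.0, amp, amp, 0.0, 0.0),
        "GAP43-like": (0.0, 0.0, amp, amp, 0.0),
    }
    size = dict(image_height_px=224, image_width_px=768, lamina_wavelength_px=384.0) if small \
        else dict(image_height_px=2048, image_width_px=2048, lamina_wavelength_px=1024.0)
    return EpitheliumModel(
        pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
        lamina_baseline_px=160.0,
        lamina_amplitude_px=8.0,
        layer_boundaries=boundaries,
        layer_names=names,
        probe_profiles=probes,
        blob_density_per_um2=density,
        blob_radius_um=sigma_um,
        background_level=background,
        noise_sd=noise_sd,
        seed=seed,
        **size,
    )


def null_calibration_model(noise_sd: float = 0.05, seed: int = 0) -> EpitheliumModel:
    """Continuous-mode single-configuration model for null-calibration studies.

    Both cohorts of a null comparison are drawn from this one configuration
    (the ``Gb1-like`` full-neuron-layer probe, iid Gaussian pixel noise, no
    blob texture) so that any detected difference is a false positive.
    """
    m = olfactory_cohort_model(blob_mode=False, small=True, noise_sd=noise_sd, seed=seed)
    return replace(m, probe_profiles={"Gb1-like": m.probe_profiles["Gb1-like"]})


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class CtDesign:
    """Designed Ct table: reference gene plus target genes with true folds."""

    genes: tuple[str, ...] = ("Gapdh", "Gb1", "Gg8", "Gg13")
    reference_gene: str = "Gapdh"
    true_rel_expression: Mapping[str, float] = field(
        default_factory=lambda: {"Gb1": 1.3, "Gg8": 0.5, "Gg13": 9.3}
    )
    n_biological: int = 3
    n_technical: int = 3
    ct_reference_mean: float = 18.0
    ct_noise_sd: float = 0.2
    group: str = "MOE"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_gene not in self.genes:
            raise ValueError(f"reference gene {self.reference_gene!r} not in genes")
        folds = dict(self.true_rel_expression)
        folds.setdefault(self.reference_gene, 1.0)
        if folds[self.reference_gene] != 1.0:
            raise ValueError("reference gene fold is 1 by construction")
        for g in self.genes:
            if g != self.reference_gene and g not in folds:
                raise ValueError(f"no designed fold for gene {g!r}")
            if folds[g] <= 0:
                raise ValueError("true_rel_expression must be positive")
        if self.n_biological < 1 or self.n_technical < 1:
            raise ValueError("replicate counts must be positive")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be nonnegative")
        object.__setattr__(self, "true_rel_expression", folds)


def generate_ct_table(design: CtDesign, seed: int | None = None) -> CtTable:
    """Simulate a long-format Ct table under the design.

    Ct(gene, sample, replicate) = ct_reference_mean - log2(fold[gene]) plus
    one independent N(0, ct_noise_sd) draw per measurement; technical
    replicates of a (sample, gene) are later collapsed by their mean.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for s in range(design.n_biological):
        sample_id = f"{design.group}_s{s + 1}"
        for gene in design.genes:
            base = design.ct_reference_mean - math.log2(design.true_rel_expression[gene])
            noise = rng.normal(0.0, design.ct_noise_sd, size=design.n_technical) \
                if design.ct_noise_sd > 0 else np.zeros(design.n_technical)
            for t in range(design.n_technical):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": design.group,
                        "gene": gene,
                        "technical_replicate": t + 1,
                        "ct": base + noise[t],
                    }
                )
    return CtTable(pd.DataFrame(rows), reference_gene=design.reference_gene)


def write_ground_truth(truth: GroundTruth, trace_path, profile_path,
                       n_profile_points: int = 501) -> None:
    """Write the lamina trace and the expected normalized profile as CSV."""
    truth.lamina_trace.to_csv(trace_path)
    x = np.linspace(0.0, 1.0, n_profile_points)
    pd.DataFrame(
        {"x": x, "intensity": truth.expected_group_profile(x), "probe": truth.probe}
    ).to_csv(profile_path, index=False)
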