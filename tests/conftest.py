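from dataclasses import replace

import numpy as np
import pytest

import episcan as e


@pytest.fixture
def one_layer_model():
    """Single uniform layer, continuous mode, noiseless: exact oracles."""
    return e.EpitheliumModel(
        image_height_px=200,
        image_width_px=300,
        pixel_size_um=0.372,
        lamina_baseline_px=150.0,
        lamina_amplitude_px=6.0,
        lamina_wavelength_px=150.0,
        layer_boundaries=(),
        layer_names=("layer",),
        probe_profiles={"p": (0.8,)},
        background_level=0.1,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def two_layer_model(one_layer_model):
    """Signal in the upper 60% of depth, nothing below: boundary oracle."""
    return replace(
        one_layer_model,
        layer_boundaries=(0.6,),
        layer_names=("upper", "lower"),
        probe_profiles={"p": (0.8, 0.0)},
    )


@pytest.fixture
def make_curve():
    """Group-level AveragedProfile from explicit grid values."""

    def _make(mean, x_grid=None, probe="p"):
        mean = np.asarray(mean, dtype=float)
        if x_grid is None:
            x_grid = np.linspace(0.0, 1.0, len(mean))
        return e.AveragedProfile(
            x_grid=np.asarray(x_grid, dtype=float),
            mean=mean,
            sem=None,
            n_contributing=3,
            level="group",
            probe=probe,
        )

    return _make


@pytest.fixture
def make_profile():
    def _make(x, y, probe="p", animal="m1", image="img1", scan="scan1", normalized=False):
        return e.IntensityProfile(
            x=np.asarray(x, dtype=float),
            y=np.asarray(y, dtype=float),
            normalized=normalized,
            meta=e.ScanMeta(animal, image, scan, probe),
        )

    return _make
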