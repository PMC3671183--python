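import math
from dataclasses import replace

import numpy as np
import pytest

import episcan as e
from episcan.synthetic import expected_blob_field


class TestEpitheliumImages:
    def test_noiseless_continuous_mode_is_piecewise_exact(self, one_layer_model):
        img, truth = e.generate_epithelium_image(one_layer_model, "p", seed=3)
        lamina = one_layer_model.lamina_row(np.arange(one_layer_model.image_width_px))
        rows = np.arange(one_layer_model.image_height_px)[:, None]
        above = rows <= lamina[None, :]
        assert np.all(img.pixels[above] == pytest.approx(0.9))
        assert np.all(img.pixels[~above] == pytest.approx(0.1))

    def test_noiseless_columns_match_design_profile(self, two_layer_model):
        img, truth = e.generate_epithelium_image(two_layer_model, "p", seed=0)
        col = 37
        lam = float(two_layer_model.lamina_row(col))
        rows = np.arange(0, int(lam))
        np.testing.assert_allclose(
            img.pixels[rows, col], truth.design_profile(rows / lam), atol=1e-12
        )

    def test_identical_seed_gives_bitwise_identical_images(self, two_layer_model):
        m = replace(two_layer_model, blob_density_per_um2=0.3, noise_sd=0.05)
        a, _ = e.generate_epithelium_image(m, "p", seed=11)
        b, _ = e.generate_epithelium_image(m, "p", seed=11)
        assert np.array_equal(a.pixels, b.pixels)
        c, _ = e.generate_epithelium_image(m, "p", seed=12)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_noise_sd_monotonically_increases_within_layer_variance(self, one_layer_model):
        variances = []
        for sd in (0.01, 0.03, 0.06):
            img, _ = e.generate_epithelium_image(
                replace(one_layer_model, noise_sd=sd), "p", seed=5
            )
            variances.append(img.pixels[:120].var())
        assert variances[0] < variances[1] < variances[2]

    def test_unknown_probe_and_bad_geometry_rejected(self, one_layer_model):
        with pytest.raises(KeyError):
            e.generate_epithelium_image(one_layer_model, "nope")
        with pytest.raises(ValueError, match="lamina exits"):
            replace(one_layer_model, lamina_baseline_px=199.0, lamina_amplitude_px=5.0)
        with pytest.raises(ValueError):
            replace(one_layer_model, image_height_px=-5)
        with pytest.raises(ValueError, match="background"):
            replace(one_layer_model, background_level=0.9)

    def test_brightfield_conversion_roundtrips(self, one_layer_model):
        img, _ = e.generate_epithelium_image(one_layer_model, "p", seed=0)
        bright = e.to_brightfield(img)
        assert not bright.inverted
        np.testing.assert_allclose(e.invert_image(bright).pixels, img.pixels, atol=1e-12)


class TestBlobMode:
    """Monte-Carlo rasterization oracle for the cell-body texture."""

    DENSITY = 0.5  # blobs / um^2
    SIGMA = 1.0  # um

    @staticmethod
    def _naive_field(rng, h, w, pixel_size, density, sigma, amp):
        """Independent rasterizer: max over all blobs via explicit distances."""
        margin = int(np.ceil(4 * sigma / pixel_size))
        lam_px = density * pixel_size**2
        n = rng.poisson(lam_px * (h + 2 * margin) * (w + 2 * margin))
        cr = rng.uniform(-margin, h + margin, n)
        cc = rng.uniform(-margin, w + margin, n)
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        d2 = (rows.ravel()[:, None] - cr) ** 2 + (cols.ravel()[:, None] - cc) ** 2
        s_px = sigma / pixel_size
        return amp * np.exp(-d2 / (2 * s_px**2)).max(axis=1).reshape(h, w)

    def test_mean_intensity_matches_closed_form_and_mc_oracle(self, one_layer_model):
        amp, bg, px = 0.8, 0.1, one_layer_model.pixel_size_um
        k = 2 * math.pi * self.DENSITY * self.SIGMA**2
        closed_form = bg + amp * k / (k + 1)
        model = replace(
            one_layer_model, blob_density_per_um2=self.DENSITY, blob_radius_um=self.SIGMA
        )
        gen_means = []
        for seed in range(60):
            img, _ = e.generate_epithelium_image(model, "p", seed=seed)
            gen_means.append(img.pixels[30:110, :].mean())  # interior of the layer
        gen_mean = np.mean(gen_means)
        rng = np.random.default_rng(999)
        mc_means = [
            bg + self._naive_field(rng, 48, 48, px, self.DENSITY, self.SIGMA, amp).mean()
            for _ in range(60)
        ]
        mc_mean = np.mean(mc_means)
        assert gen_mean == pytest.approx(closed_form, rel=0.05)
        assert mc_mean == pytest.approx(closed_form, rel=0.05)
        assert gen_mean == pytest.approx(mc_mean, rel=0.05)

    def test_expected_blob_field_reduces_to_closed_form_far_from_edges(self):
        k = 2 * math.pi * self.DENSITY * self.SIGMA**2
        val = expected_blob_field(
            np.array([50.0]), [(0.0, 100.0)], 1.0, self.DENSITY, self.SIGMA
        )[0]
        assert val == pytest.approx(k / (k + 1), abs=1e-3)

    def test_expected_blob_field_edge_profile_matches_simulation(self, one_layer_model):
        """The Boolean-model expectation tracks the simulated boundary spread."""
        model = replace(
            one_layer_model,
            layer_boundaries=(0.6,),
            layer_names=("upper", "lower"),
            probe_profiles={"p": (0.8, 0.0)},
            blob_density_per_um2=self.DENSITY,
            blob_radius_um=self.SIGMA,
        )
        cols = np.arange(model.image_width_px)
        sims = []
        for seed in range(40):
            img, truth = e.generate_epithelium_image(model, "p", seed=seed)
            lam = np.asarray(model.lamina_row(cols))
            # sample a fixed band of normalized depths across all columns
            xs = np.linspace(0.45, 0.75, 61)
            rows = np.clip(np.round(xs[:, None] * lam[None, :]).astype(int), 0, None)
            sims.append(img.pixels[rows, cols].mean(axis=1))
        sim_profile = np.mean(sims, axis=0)
        depth = model.lamina_baseline_px * model.pixel_size_um
        exp_profile = model.background_level + expected_blob_field(
            np.linspace(0.45, 0.75, 61) * depth, [(0.0, 0.6 * depth)], 0.8,
            self.DENSITY, self.SIGMA,
        )
        np.testing.assert_allclose(sim_profile, exp_profile, atol=0.03)


class TestCtTables:
    def test_equal_expression_gives_reference_ct(self):
        design = e.CtDesign(
            genes=("Gapdh", "geneA"), true_rel_expression={"geneA": 1.0}, ct_noise_sd=0.0
        )
        table = e.generate_ct_table(design, seed=0)
        wide = table.collapsed().pivot(index="sample_id", columns="gene", values="ct")
        np.testing.assert_allclose(wide["geneA"], wide["Gapdh"], atol=1e-12)

    def test_eightfold_expression_shifts_ct_by_three_cycles(self):
        design = e.CtDesign(
            genes=("Gapdh", "geneA"), true_rel_expression={"geneA": 8.0},
            ct_noise_sd=0.0, ct_reference_mean=18.0,
        )
        table = e.generate_ct_table(design, seed=0)
        cts = table.data.loc[table.data["gene"] == "geneA", "ct"]
        np.testing.assert_allclose(cts, 15.0, atol=1e-12)

    def test_noiseless_tables_invert_exactly_under_delta_ct(self):
        design = replace(e.CtDesign(), ct_noise_sd=0.0)
        rel = e.relative_expression(e.generate_ct_table(design, seed=4))
        for gene, fold in design.true_rel_expression.items():
            got = float(rel.loc[rel["gene"] == gene, "fold"].iloc[0])
            assert got == pytest.approx(fold, abs=1e-12)

    def test_seeded_reproducibility(self):
        d = e.CtDesign()
        a = e.generate_ct_table(d, seed=7).data
        b = e.generate_ct_table(d, seed=7).data
        assert a.equals(b)

    def test_design_validation(self):
        with pytest.raises(ValueError, match="reference gene"):
            e.CtDesign(genes=("geneA",), reference_gene="Gapdh")
        with pytest.raises(ValueError, match="positive"):
            e.CtDesign(genes=("Gapdh", "g"), true_rel_expression={"g": -1.0})
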