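import numpy as np
import pytest
from scipy import stats
from scipy.interpolate import CubicSpline

import episcan as e


def brute_force_ks_d(a, b):
    """Sup over pooled thresholds of |ECDF1 - ECDF2| (independent oracle)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = 0.0
    for t in np.concatenate([a, b]):
        d = max(d, abs((a <= t).mean() - (b <= t).mean()))
    return d


class TestAreaIntegral:
    def test_constant_curve_integrates_to_window_width(self, make_curve):
        c = make_curve(np.ones(100))
        w = e.MarkerWindow(0.63, 0.93)
        assert e.area_integral(c, w).value == pytest.approx(0.30, abs=1e-12)

    def test_linear_curve_full_window(self, make_curve):
        c = make_curve(np.linspace(0, 1, 100))
        assert e.area_integral(c, e.MarkerWindow(0.0, 1.0)).value == pytest.approx(0.5)

    def test_endpoint_insertion_matches_dense_riemann_oracle(self, make_curve):
        rng = np.random.default_rng(42)
        for _ in range(20):
            knots = np.linspace(0, 1, 8)
            spline = CubicSpline(knots, rng.uniform(0.1, 1.0, 8))
            grid = np.linspace(0, 1, 100)
            c = make_curve(spline(grid))
            x1, x2 = sorted(rng.uniform(0.02, 0.98, 2))
            if x2 - x1 < 0.05:
                continue
            w = e.MarkerWindow(float(x1), float(x2))
            got = e.area_integral(c, w).value
            # Riemann midpoint sum on the same piecewise-linear curve
            xs = np.linspace(x1, x2, 1_000_001)
            mids = (xs[:-1] + xs[1:]) / 2
            oracle = np.sum(np.interp(mids, grid, c.mean)) * (x2 - x1) / 1_000_000
            assert got == pytest.approx(oracle, abs=1e-4)

    def test_additivity_is_exact(self, make_curve):
        rng = np.random.default_rng(1)
        c = make_curve(rng.uniform(0, 1, 100))
        whole = e.area_integral(c, e.MarkerWindow(0.2, 0.8)).value
        for m in (0.3, 0.41237, 0.5, 0.79):
            left = e.area_integral(c, e.MarkerWindow(0.2, m)).value
            right = e.area_integral(c, e.MarkerWindow(m, 0.8)).value
            assert left + right == pytest.approx(whole, abs=1e-12)

    def test_pointwise_domination_orders_integrals(self, make_curve):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 0.8, 100)
        lo, hi = make_curve(base), make_curve(base + 0.1)
        for w in (e.MarkerWindow(0.1, 0.4), e.MarkerWindow(0.63, 0.93)):
            assert e.area_integral(hi, w).value >= e.area_integral(lo, w).value

    def test_bad_windows_rejected(self, make_curve):
        c = make_curve(np.ones(10), x_grid=np.linspace(0.2, 0.8, 10))
        with pytest.raises(ValueError):
            e.MarkerWindow(0.9, 0.6)
        with pytest.raises(ValueError, match="outside curve grid"):
            e.area_integral(c, e.MarkerWindow(0.1, 0.5))


class TestDeriveWindow:
    def test_rectangular_pulse_recovers_its_support(self, make_curve):
        x = np.linspace(0, 1, 101)
        c = make_curve(np.where((x >= 0.6) & (x <= 0.9), 1.0, 0.0), x_grid=x)
        w = e.derive_window(c)
        assert w.x1 == pytest.approx(0.6, abs=0.011)
        assert w.x2 == pytest.approx(0.9, abs=0.011)
        assert w.source == "half_max_of_marker"

    def test_triangular_peak_half_max_crossings(self, make_curve):
        x = np.linspace(0, 1, 201)
        peak, halfwidth = 0.78, 0.15
        c = make_curve(np.clip(1 - np.abs(x - peak) / (2 * halfwidth), 0, None), x_grid=x)
        w = e.derive_window(c)
        assert w.x1 == pytest.approx(peak - halfwidth, abs=0.006)
        assert w.x2 == pytest.approx(peak + halfwidth, abs=0.006)

    def test_constant_curve_has_no_crossing(self, make_curve):
        with pytest.raises(ValueError):
            e.derive_window(make_curve(np.ones(50)))

    def test_bimodal_curve_requires_explicit_window(self, make_curve):
        x = np.linspace(0, 1, 201)
        y = np.exp(-((x - 0.3) ** 2) / 0.002) + np.exp(-((x - 0.7) ** 2) / 0.002)
        with pytest.raises(ValueError, match="disjoint"):
            e.derive_window(make_curve(y, x_grid=x))


class TestKS:
    def test_identical_inputs_give_zero_distance(self, make_curve):
        c = make_curve(np.linspace(0.2, 1.0, 31))
        res = e.ks_compare(c, c, e.MarkerWindow(0.0, 1.0))
        assert res.D == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports_give_distance_one(self, make_curve):
        a = make_curve(np.array([0.1, 0.2, 0.3]))
        b = make_curve(np.array([0.7, 0.8, 0.9]))
        res = e.ks_compare(a, b, e.MarkerWindow(0.0, 1.0))
        assert res.D == 1.0

    def test_statistic_matches_brute_force_enumeration(self, make_curve):
        rng = np.random.default_rng(7)
        for _ in range(100):
            va, vb = rng.random(8), rng.random(8)
            res = e.ks_compare(
                make_curve(va, x_grid=np.linspace(0, 1, 8)),
                make_curve(vb, x_grid=np.linspace(0, 1, 8)),
                e.MarkerWindow(0.0, 1.0),
            )
            assert res.D == pytest.approx(brute_force_ks_d(va, vb), abs=1e-12)

    def test_invariant_under_monotone_transforms(self, make_curve):
        rng = np.random.default_rng(8)
        va, vb = rng.random(20), rng.random(20) * 0.8
        w = e.MarkerWindow(0.0, 1.0)
        base = e.ks_compare(make_curve(va), make_curve(vb), w)
        for f in (np.exp, np.sqrt, lambda v: 3 * v - 7, lambda v: v**3):
            res = e.ks_compare(make_curve(f(va)), make_curve(f(vb)), w)
            assert res.D == pytest.approx(base.D, abs=1e-12)

    def test_exact_small_sample_p_matches_scipy_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a, b = rng.random(7), rng.random(6)
            p_exact = e.ks_exact_p(a, b)
            p_scipy = stats.ks_2samp(a, b, method="exact").pvalue
            assert p_exact == pytest.approx(p_scipy, abs=1e-9)

    def test_density_cdf_mode(self, make_curve):
        x = np.linspace(0.63, 0.93, 31)
        w = e.MarkerWindow(0.63, 0.93)
        flat = make_curve(np.ones(31), x_grid=x)
        res = e.ks_compare(flat, flat, w, mode="density_cdf")
        assert res.D == 0.0 and res.p_is_placeholder
        ramp = make_curve(np.linspace(0, 1, 31), x_grid=x)
        res2 = e.ks_compare(flat, ramp, w, mode="density_cdf")
        # |u - u^2| on [0,1] peaks at 1/4
        assert res2.D == pytest.approx(0.25, abs=0.01)
        zero = make_curve(np.zeros(31), x_grid=x)
        with pytest.raises(ValueError, match="all-zero"):
            e.ks_compare(flat, zero, w, mode="density_cdf")


class TestCompareIntegrals:
    def test_constant_curves_report_known_ratio(self, make_curve):
        curves = {"A": make_curve(np.ones(100)), "B": make_curve(np.full(100, 0.5))}
        integrals, ratios = e.compare_windowed_integrals(curves, e.MarkerWindow(0.63, 0.93))
        vals = dict(zip(integrals["probe"], integrals["integral"]))
        assert vals["A"] == pytest.approx(0.30, abs=1e-12)
        assert vals["B"] == pytest.approx(0.15, abs=1e-12)
        r = {(p, q): v for p, q, v in ratios.itertuples(index=False)}
        assert r[("A", "B")] == pytest.approx(2.0)
        assert r[("B", "A")] == pytest.approx(0.5)

    def test_self_ratio_is_one(self, make_curve):
        c = make_curve(np.linspace(0.1, 1, 100))
        curves = {"A": c, "B": c}
        _, ratios = e.compare_windowed_integrals(curves, e.MarkerWindow(0.2, 0.9))
        assert np.allclose(ratios["ratio"], 1.0)
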