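"""Cross-basis construction, DLNM fitting, centering and definition
selection, checked against explicit-loop oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

import heatrisk as hr
from heatrisk.dlnm import gaussian_aic, lag_basis
from _oracles import naive_crossbasis, naive_cumulative


def random_hwii_series(rng, n=400, n_events=8):
    """Mostly-zero exposure series with constant-valued event blocks."""
    h = np.zeros(n)
    for _ in range(n_events):
        start = int(rng.integers(0, n - 6))
        dur = int(rng.integers(1, 6))
        h[start : start + dur] = float(rng.uniform(0.5, 20.0))
    return h


class TestCrossBasis:
    def test_all_zero_series_with_center_zero_is_zero_matrix(self):
        spec = hr.CrossBasisSpec(center=0.0)
        cb = hr.build_crossbasis(np.zeros(50), spec)
        assert np.allclose(cb.matrix, 0.0)

    def test_constant_lag_basis_reduces_to_moving_sum(self):
        rng = np.random.default_rng(0)
        h = random_hwii_series(rng)
        spec = hr.CrossBasisSpec(df_var=2, df_lag=1, max_lag=3)
        cb = hr.build_crossbasis(h, spec)
        V = cb.var_basis_centered(h)
        moving = np.zeros_like(V)
        for lag in range(4):
            moving[lag:] += V[: len(h) - lag]
        assert np.allclose(cb.matrix, moving, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hwii_series(rng, n=80)
        spec = hr.CrossBasisSpec(
            df_var=int(rng.integers(1, 4)), df_lag=int(rng.integers(1, 4)),
            max_lag=int(rng.integers(2, 5)),
            center=float(rng.uniform(0, h.max())),
        )
        cb = hr.build_crossbasis(h, spec)
        naive = naive_crossbasis(h, cb.var_knots, cb.lag_matrix, spec.center)
        assert np.allclose(cb.matrix[cb.valid], naive[cb.valid], atol=1e-12)
        # cumulative predictions against the explicit-lag-summation oracle
        beta = rng.normal(size=cb.matrix.shape[1])
        grid = np.linspace(0, h.max(), 15)
        W = cb.cumulative_weights(grid)
        assert np.allclose(
            W @ beta,
            naive_cumulative(grid, beta, cb.var_knots, cb.lag_matrix, spec.center),
            atol=1e-10)

    def test_first_rows_flagged_and_center_range_checked(self):
        h = random_hwii_series(np.random.default_rng(1))
        cb = hr.build_crossbasis(h, hr.CrossBasisSpec(max_lag=3))
        assert (~cb.valid[:3]).all() and cb.valid[3:].all()
        with pytest.raises(ValueError, match="center"):
            hr.build_crossbasis(h, hr.CrossBasisSpec(center=h.max() + 1))

    def test_lag_basis_shapes(self):
        assert lag_basis(3, 1).shape == (4, 1)
        C = lag_basis(3, 3)
        assert C.shape == (4, 3)
        assert np.allclose(C[:, 0], 1.0)


class TestFit:
    def test_aic_matches_stated_convention(self, demo_fit):
        fit = demo_fit["fit"]
        n, k = fit.n_obs, len(fit.params)
        rss = fit.sigma2 * (n - k)
        assert fit.aic == pytest.approx(n * np.log(rss / n) + 2 * (k + 1), rel=1e-12)
        assert np.isfinite(fit.aic)

    def test_covariance_symmetric_psd(self, demo_fit):
        cov = demo_fit["fit"].cov
        assert np.allclose(cov, cov.T, atol=1e-14)
        assert np.linalg.eigvalsh(cov).min() > -1e-18

    def test_rank_deficient_design_names_columns(self, demo_fit):
        records = demo_fit["records"].copy()
        records["rh"] = records["holiday"]  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="rh|holiday"):
            hr.fit_dlnm(records, demo_fit["events"], demo_fit["spec"])

    def test_missing_column_is_named(self, demo_fit):
        records = demo_fit["records"].drop(columns=["rh"])
        with pytest.raises(ValueError, match="rh"):
            hr.fit_dlnm(records, demo_fit["events"], demo_fit["spec"])

    def test_aic_invariant_to_affine_confounder_rescaling(self, demo_fit):
        records = demo_fit["records"].copy()
        fit1 = hr.fit_dlnm(records, demo_fit["events"], demo_fit["spec"])
        records["rh"] = 3.0 * records["rh"] + 10.0
        fit2 = hr.fit_dlnm(records, demo_fit["events"], demo_fit["spec"])
        assert fit2.aic == pytest.approx(fit1.aic, abs=1e-6)

    @pytest.mark.parametrize("confounder", ["dow", "holiday"])
    def test_confounder_only_truth_recovered(self, confounder):
        # with a single multiplicative confounder the additive truth is exact
        kw = dict(trend_slope=0.0, season_amplitude=0.0,
                  vuln_truth=(hr.VulnTruth("linear", 0.0),) * 2,
                  n_years=20, start_year=1990, seed=3)
        if confounder == "dow":
            kw["dow_effects"] = (1.0, 0.97, 0.96, 0.98, 0.99, 1.03, 1.05)
            kw["holiday_effect"] = 1.0
        else:
            kw["dow_effects"] = (1.0,) * 7
            kw["holiday_effect"] = 1.08
        cfg = hr.demo_config(**kw)
        ds = hr.generate_dataset(cfg)
        events = hr.detect_events(
            ds.records, cfg.truth_definition,
            threshold=ds.truth["truth_threshold"])
        fit = hr.fit_dlnm(ds.records, events, hr.CrossBasisSpec(),
                          age_group="65plus")
        share, base = cfg.age_shares[1], cfg.baseline_rate[1]
        se = np.sqrt(np.diag(fit.cov))
        if confounder == "dow":
            for d, name in enumerate(
                    ["dow_tue", "dow_wed", "dow_thu", "dow_fri", "dow_sat",
                     "dow_sun"], start=1):
                i = fit.columns.index(name)
                truth = share * base * (cfg.dow_effects[d] - cfg.dow_effects[0])
                assert abs(fit.params[i] - truth) < 3 * se[i]
        else:
            i = fit.columns.index("holiday")
            truth = share * base * (cfg.holiday_effect - 1.0)
            assert abs(fit.params[i] - truth) < 3 * se[i]


class TestCurve:
    def test_curve_is_zero_at_center_and_bands_ordered(self, demo_fit):
        curve = demo_fit["curve"]
        i = int(np.argmin(np.abs(curve.grid - curve.center)))
        assert curve.grid[i] == curve.center
        assert curve.central[i] == 0.0
        assert curve.lower95[i] == 0.0 and curve.upper95[i] == 0.0
        assert (curve.lower95 <= curve.central + 1e-15).all()
        assert (curve.central <= curve.upper95 + 1e-15).all()

    def test_ci_width_shrinks_with_sample_size(self):
        # 4x the data -> CI width at a fixed exposure roughly halves.
        # Fixed center and a fixed evaluation point isolate the 1/sqrt(n)
        # scaling from per-dataset centering/range differences.
        ratios = []
        for seed in range(10):
            widths = {}
            for n_years in (10, 40):
                cfg = hr.demo_config(n_years=n_years, start_year=1970, seed=seed)
                ds = hr.generate_dataset(cfg)
                events = hr.detect_events(
                    ds.records, cfg.truth_definition,
                    threshold=ds.truth["truth_threshold"])
                fit = hr.fit_dlnm(ds.records, events, hr.CrossBasisSpec(),
                                  age_group="65plus")
                curve = hr.cumulative_curve(fit, grid=np.linspace(0, 8, 30))
                w = curve.upper95 - curve.lower95
                widths[n_years] = np.interp(5.0, curve.grid, w)
            ratios.append(widths[40] / widths[10])
        assert 0.375 < np.mean(ratios) < 0.625

    def test_recovery_error_decreases_with_more_years(self):
        truth = hr.VulnTruth("hockey", 1.2e-5, breakpoint=3.0)
        mads = {}
        for n_years in (8, 32):
            vals = []
            for seed in range(3):
                cfg = hr.demo_config(
                    n_years=n_years, start_year=1980, seed=seed,
                    vuln_truth=(hr.VulnTruth("linear", 0.0), truth))
                ds = hr.generate_dataset(cfg)
                events = hr.detect_events(
                    ds.records, cfg.truth_definition,
                    threshold=ds.truth["truth_threshold"])
                fit, curve = hr.fit_vulnerability(
                    ds.records, events, hr.CrossBasisSpec(), age_group="65plus")
                share = cfg.age_shares[1]
                target = share * (truth(curve.grid) - truth(curve.center))
                vals.append(np.mean(np.abs(curve.central - target)))
            mads[n_years] = np.mean(vals)
        assert mads[32] < mads[8]


class TestCenter:
    def _manual_fit(self, beta, cb):
        k = len(beta)
        return hr.DLNMFit(
            params=np.asarray(beta, dtype=float), cov=np.eye(k) * 1e-12,
            columns=[f"cb_{j}" for j in range(k)], cb_slice=slice(0, k),
            crossbasis=cb, aic=0.0, n_obs=0, sigma2=1.0, age_group="test")

    def test_flat_curve_takes_leftmost_gridpoint(self):
        h = random_hwii_series(np.random.default_rng(2))
        cb = hr.build_crossbasis(h, hr.CrossBasisSpec())
        fit = self._manual_fit(np.zeros(cb.matrix.shape[1]), cb)
        assert hr.find_center(fit) == pytest.approx(cb.positive_min)

    def test_monotone_curve_centers_at_grid_minimum(self):
        h = random_hwii_series(np.random.default_rng(3))
        cb = hr.build_crossbasis(h, hr.CrossBasisSpec())
        grid = np.linspace(cb.positive_min, h.max(), 50)
        W = cb.cumulative_weights(grid)
        beta, *_ = np.linalg.lstsq(W, grid - grid[0], rcond=None)  # increasing
        fit = self._manual_fit(beta, cb)
        assert hr.find_center(fit) == pytest.approx(cb.positive_min)

    def test_u_shaped_truth_trough_recovered(self):
        h = random_hwii_series(np.random.default_rng(4), n_events=12)
        cb = hr.build_crossbasis(h, hr.CrossBasisSpec(df_var=3))
        # a U-shaped natural cubic spline on the same knots lies in the
        # span of the cumulative weights, so the representation is exact
        knots = cb.var_knots
        u_vals = (knots - 0.6 * knots[-1]) ** 2
        target_fn = CubicSpline(knots, u_vals, bc_type="natural")
        grid = np.linspace(cb.positive_min, h.max(), 60)
        W = cb.cumulative_weights(grid)
        beta, *_ = np.linalg.lstsq(
            W, target_fn(grid) - target_fn(cb.spec.center), rcond=None)
        fit = self._manual_fit(beta, cb)
        dense = np.linspace(cb.positive_min, h.max(), 2000)
        trough = dense[np.argmin(target_fn(dense))]
        step = grid[1] - grid[0]
        assert abs(hr.find_center(fit, n_grid=60) - trough) <= step + 1e-9


class TestSelection:
    def test_singleton_catalogue_returned(self, demo_fit):
        defn = demo_fit["definition"]
        best, table = hr.select_definition(
            demo_fit["records"], [defn], hr.CrossBasisSpec())
        assert best.id == defn.id
        assert len(table) == 1

    def test_ties_break_in_catalogue_order(self, demo_fit):
        d1 = dataclasses.replace(demo_fit["definition"], id="first")
        d2 = dataclasses.replace(demo_fit["definition"], id="second")
        best, table = hr.select_definition(
            demo_fit["records"], [d1, d2], hr.CrossBasisSpec())
        assert best.id == "first"
        assert table["aic"].iloc[0] == table["aic"].iloc[1]

    def test_zero_event_definitions_marked_non_fittable(self, demo_fit):
        never = hr.HWDefinition(id="never", metric="max",
                                threshold_kind="absolute_celsius",
                                threshold_value=90.0, min_duration=3)
        best, table = hr.select_definition(
            demo_fit["records"], [never, demo_fit["definition"]],
            hr.CrossBasisSpec())
        assert best.id == demo_fit["definition"].id
        row = table[table["id"] == "never"].iloc[0]
        assert row["n_events"] == 0 and np.isnan(row["aic"])

    def test_packaged_catalogue_has_sixteen_definitions(self):
        cat = hr.default_catalogue()
        assert len(cat) == 16
        assert len({d.id for d in cat}) == 16


class TestSweepAndPercentiles:
    def test_default_sweep_emits_36_base_fits(self, demo_fit):
        table, curves = hr.sensitivity_sweep(
            demo_fit["records"], demo_fit["events"], n_grid=20)
        assert len(table) == 36
        # df_lag=5 over max_lag=3 has more basis columns than lag points
        assert int(table["aic"].isna().sum()) == 3
        assert len(curves) == 33

    def test_singleton_sweep_equals_direct_fit(self, demo_fit):
        table, curves = hr.sensitivity_sweep(
            demo_fit["records"], demo_fit["events"],
            df_var_grid=(2,), df_lag_grid=(3,), max_lag_grid=(3,), n_grid=50)
        assert table["aic"].iloc[0] == pytest.approx(demo_fit["fit"].aic, rel=1e-12)

    def test_independent_noise_confounder_barely_moves_curve(self, demo_fit):
        records = demo_fit["records"].copy()
        rng = np.random.default_rng(0)
        records["white_noise"] = rng.normal(size=len(records))
        _, base_curve = hr.fit_vulnerability(
            records, demo_fit["events"], hr.CrossBasisSpec(), age_group="65plus")
        _, noisy_curve = hr.fit_vulnerability(
            records, demo_fit["events"], hr.CrossBasisSpec(), age_group="65plus",
            extra_confounders=("white_noise",))
        half_width = 0.5 * (base_curve.upper95 - base_curve.lower95)
        moved = np.abs(noisy_curve.central - base_curve.central)
        assert (moved <= np.maximum(half_width, 1e-12)).all()

    def test_percentile_axis_endpoints_and_monotonicity(self):
        curve = hr.VulnerabilityCurve(
            grid=np.array([1.0, 2.0, 3.0, 5.0]), central=np.zeros(4),
            lower95=np.zeros(4), upper95=np.zeros(4), age_group="x",
            center=1.0, observed_range=(1.0, 5.0))
        out = hr.percentile_axis(curve, [1.0, 2.0, 5.0])
        assert out.percentiles[0] == 0.0
        assert out.percentiles[1] == 50.0
        assert out.percentiles[-1] == 100.0
        assert (np.diff(out.percentiles) >= 0).all()
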