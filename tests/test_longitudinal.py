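"""Statistical layer: summaries, panel models with HAC variance, LOESS,
dynamical correlation, Pearson, chi-square. Oracles are independent
brute-force computations or statsmodels cross-checks."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from conftest import make_panel, make_xy_panel
from venticomp import (bootstrap_dyncorr, chi_square_obstruction,
                       dynamical_correlation, fit_random_effects_panel,
                       loess_trend, newey_west_vcov, pearson_r,
                       summarize_median_iqr)
from venticomp.longitudinal import adf_stationarity_screen, default_nw_lag


class TestSummaries:
    def test_median_iqr_examples(self):
        panel = make_panel({"s1": [1, 2, 3, 4, 5]}, parameter="pip")
        out = summarize_median_iqr(panel)
        assert out.loc[0, "median"] == 3.0
        assert out.loc[0, "iqr"] == 2.0

    def test_constant_values(self):
        panel = make_panel({"s1": [7.0] * 10}, parameter="pip")
        out = summarize_median_iqr(panel)
        assert out.loc[0, "median"] == 7.0
        assert out.loc[0, "iqr"] == 0.0

    def test_empty_raises(self):
        panel = make_panel({"s1": [1.0]}, parameter="pip")
        with pytest.raises(ValueError):
            summarize_median_iqr(panel, parameter="leak")


class TestNeweyWest:
    @staticmethod
    def _ols(X, y):
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        return b, y - X @ b

    def test_lag_zero_equals_white(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = X @ [1.0, 2.0] + rng.normal(size=80) * (1 + np.abs(X[:, 1]))
        _, r = self._ols(X, y)
        V = newey_west_vcov(X, r, lag=0)
        res = sm.OLS(y, X).fit()
        Vw = sm.stats.sandwich_covariance.cov_white_simple(
            res, use_correction=False)
        np.testing.assert_allclose(V, Vw, rtol=1e-10)

    def test_matches_statsmodels_hac(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(120), rng.normal(size=120)])
        e = np.convolve(rng.normal(size=130), np.ones(5) / 5, "valid")[:120]
        y = X @ [0.5, -1.0] + e
        _, r = self._ols(X, y)
        res = sm.OLS(y, X).fit()
        for lag in (1, 3, 6):
            V = newey_west_vcov(X, r, lag=lag)
            Vh = sm.stats.sandwich_covariance.cov_hac_simple(
                res, nlags=lag, use_correction=False)
            np.testing.assert_allclose(V, Vh, rtol=1e-10)

    def test_hand_computed_four_observations_lag_one(self):
        # independent oracle: explicit Bartlett-weighted double sum
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        e = np.array([0.5, -1.0, 0.25, 2.0])
        lag = 1
        z = X[:, 0] * e
        s = sum(z[t] * z[t] for t in range(4))
        w1 = 1.0 - 1.0 / (lag + 1.0)
        s += 2.0 * w1 * sum(z[t] * z[t - 1] for t in range(1, 4))
        bread = 1.0 / float(X[:, 0] @ X[:, 0])
        expected = bread * s * bread
        V = newey_west_vcov(X, e, lag=1)
        assert V[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_iid_large_n_approaches_ols_variance(self):
        rng = np.random.default_rng(5)
        n = 4000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 1.0] + rng.normal(size=n)
        _, r = self._ols(X, y)
        V = newey_west_vcov(X, r, lag=5)
        s2 = r @ r / (n - 2)
        V_ols = s2 * np.linalg.inv(X.T @ X)
        np.testing.assert_allclose(np.diag(V), np.diag(V_ols), rtol=0.1)

    def test_lag_exceeding_series_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError):
            newey_west_vcov(X, np.ones(4), lag=4)
        with pytest.raises(ValueError):
            newey_west_vcov(X, np.ones(4), lag=-1)


def _gen_null_panel(rng, n_per=18, T=40, offset=0.0, ar=0.0, su=1.0, se=1.5):
    rows = []
    for arm, gname in ((0, "M"), (1, "B")):
        for s in range(n_per):
            u = rng.normal(0, su)
            innov = rng.normal(0, se, T)
            eps = np.empty(T)
            prev = 0.0
            for t in range(T):
                prev = ar * prev + innov[t]
                eps[t] = prev
            vals = 10 + offset * arm + u + eps
            rows += [(f"{gname}{s}", t + 1, "pip", vals[t], gname, "S")
                     for t in range(T)]
    return pd.DataFrame(rows, columns=["subject_id", "breath_index",
                                       "parameter", "value", "group",
                                       "duration_class"])


class TestPanelModel:
    def test_zero_between_variance_equals_pooled_ols(self):
        # subject means exactly equal within arm -> sigma2_u estimate is 0
        base = np.array([1.0, 2.0, 3.0, 4.0])
        curves = {f"M{i}": np.roll(base, i) for i in range(3)}
        curves |= {f"B{i}": np.roll(base + 2.0, i) for i in range(3)}
        panel = make_panel(curves, parameter="pip")
        panel["group"] = [sid[0] for sid in panel.subject_id]
        with pytest.warns(UserWarning, match="pooled OLS"):
            fit = fit_random_effects_panel(panel, "pip")
        assert fit.method == "pooled-ols"
        y = panel.value.to_numpy()
        g = (panel.group == "M").to_numpy()
        assert fit.coef == pytest.approx(y[g].mean() - y[~g].mean(), abs=1e-9)

    def test_recovers_group_offset(self):
        rng = np.random.default_rng(10)
        panel = _gen_null_panel(rng, offset=5.0)
        fit = fit_random_effects_panel(panel, "pip")
        # coding is M minus B (sorted levels); offset was put on arm B
        assert fit.contrast_label == "M-B"
        assert fit.coef == pytest.approx(-5.0, abs=1.5)
        assert fit.p_value < 0.01

    def test_power_under_ar1_errors(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(40):
            panel = _gen_null_panel(rng, offset=5.0, ar=0.5, se=2.0)
            if fit_random_effects_panel(panel, "pip").p_value < 0.05:
                hits += 1
        assert hits / 40 > 0.8

    def test_unbiased_under_null(self):
        rng = np.random.default_rng(13)
        coefs = [fit_random_effects_panel(
            _gen_null_panel(rng, n_per=10, T=20), "pip").coef
            for _ in range(120)]
        resid_sd = 1.5
        assert abs(np.mean(coefs)) < 0.05 * resid_sd + 3 * np.std(coefs) / np.sqrt(120)

    def test_requires_two_subjects_per_arm(self):
        panel = make_panel({"M1": [1, 2], "B1": [3, 4]})
        panel["group"] = [s[0] for s in panel.subject_id]
        panel["parameter"] = "pip"
        with pytest.raises(ValueError):
            fit_random_effects_panel(panel, "pip")

    def test_default_lag_rule(self):
        assert default_nw_lag(100) == 4
        assert default_nw_lag(40) == 3


class TestLoess:
    def test_exact_on_line(self):
        panel = make_panel({f"s{i}": 2.0 * np.arange(1, 31) + 1.0
                            for i in range(6)}, parameter="pip")
        tc = loess_trend(panel, "pip")
        np.testing.assert_allclose(tc.smoothed_mean,
                                   2.0 * tc.breath_index + 1.0, atol=1e-6)

    def test_constant_data_constant_curve_small_se(self):
        panel = make_panel({f"s{i}": [5.0] * 20 for i in range(30)},
                           parameter="pip")
        tc = loess_trend(panel, "pip")
        np.testing.assert_allclose(tc.smoothed_mean, 5.0, atol=1e-9)
        assert np.all(tc.standard_error < 1e-9)

    def test_min_subject_rule_drops_sparse_indices(self):
        curves = {f"s{i}": [1.0] * 20 for i in range(5)}
        curves["s5"] = [1.0] * 25  # indices 21..25 observed by 1 subject
        panel = make_panel(curves, parameter="pip")
        tc = loess_trend(panel, "pip")
        assert tc.breath_index.max() == 20

    def test_matches_statsmodels_lowess(self):
        rng = np.random.default_rng(21)
        curves = {f"s{i}": np.sin(np.arange(1, 41) / 6.0)
                  + rng.normal(0, 0.1, 40) for i in range(6)}
        panel = make_panel(curves, parameter="pip")
        tc = loess_trend(panel, "pip", span=0.5)
        x = panel.breath_index.to_numpy(dtype=float)
        y = panel.value.to_numpy()
        lo = sm.nonparametric.lowess(y, x, frac=0.5, it=0, delta=0)
        ref = {xx: yy for xx, yy in lo}
        diffs = [abs(m - ref[float(b)])
                 for b, m in zip(tc.breath_index, tc.smoothed_mean)]
        assert max(diffs) < 1e-8

    def test_invariant_to_point_duplication(self):
        rng = np.random.default_rng(22)
        curves = {f"s{i}": rng.normal(3, 1, 15) for i in range(6)}
        panel = make_panel(curves, parameter="pip")
        doubled = pd.concat([panel, panel.assign(
            subject_id=panel.subject_id + "_dup")], ignore_index=True)
        a = loess_trend(panel, "pip")
        b = loess_trend(doubled, "pip")
        np.testing.assert_allclose(a.smoothed_mean, b.smoothed_mean,
                                   atol=1e-9)

    def test_too_few_indices_rejected(self):
        panel = make_panel({f"s{i}": [1.0, 2.0] for i in range(6)},
                           parameter="pip")
        with pytest.raises(ValueError):
            loess_trend(panel, "pip")


class TestDynamicalCorrelation:
    def test_identical_curves_give_one(self):
        rng = np.random.default_rng(31)
        x = {f"s{i}": rng.normal(size=8) for i in range(4)}
        panel = make_xy_panel(x, x)
        assert dynamical_correlation(panel, "x", "y").rho == \
            pytest.approx(1.0, abs=1e-12)

    def test_negated_curves_give_minus_one(self):
        rng = np.random.default_rng(32)
        x = {f"s{i}": rng.normal(size=8) for i in range(4)}
        y = {k: -v for k, v in x.items()}
        panel = make_xy_panel(x, y)
        assert dynamical_correlation(panel, "x", "y").rho == \
            pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_toy(self):
        # 3 subjects x 5 indices, explicit loop-based oracle
        rng = np.random.default_rng(33)
        X = rng.normal(size=(3, 5))
        Y = rng.normal(size=(3, 5))

        Xc = np.array([row - row.mean() for row in X])
        Yc = np.array([row - row.mean() for row in Y])
        Xc = Xc - Xc.mean(axis=0)
        Yc = Yc - Yc.mean(axis=0)
        rhos = []
        for i in range(3):
            nx = np.sqrt(sum(v * v for v in Xc[i]))
            ny = np.sqrt(sum(v * v for v in Yc[i]))
            rhos.append(sum(a * b for a, b in zip(Xc[i], Yc[i])) / (nx * ny))
        expected = np.mean(rhos)

        panel = make_xy_panel({f"s{i}": X[i] for i in range(3)},
                              {f"s{i}": Y[i] for i in range(3)})
        assert dynamical_correlation(panel, "x", "y").rho == \
            pytest.approx(expected, abs=1e-10)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(34)
        for trial in range(10):
            x = {f"s{i}": rng.normal(size=6) for i in range(5)}
            y = {f"s{i}": rng.normal(size=6) for i in range(5)}
            rho = dynamical_correlation(make_xy_panel(x, y), "x", "y").rho
            assert -1.0 <= rho <= 1.0

    @given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 50))
    @hsettings(max_examples=40, derandomize=True)
    def test_affine_invariance(self, scale, seed):
        # common positive scale, per-subject offsets on both curves
        rng = np.random.default_rng(seed)
        x = {f"s{i}": rng.normal(size=6) for i in range(4)}
        y = {f"s{i}": rng.normal(size=6) for i in range(4)}
        base = dynamical_correlation(make_xy_panel(x, y), "x", "y").rho
        offs = {k: float(rng.normal()) for k in x}
        x2 = {k: scale * v + offs[k] for k, v in x.items()}
        y2 = {k: scale * v - offs[k] for k, v in y.items()}
        moved = dynamical_correlation(make_xy_panel(x2, y2), "x", "y").rho
        assert moved == pytest.approx(base, abs=1e-9)

    def test_zero_variance_subject_excluded_with_warning(self):
        x = {"s0": [1.0, 2.0, 3.0], "s1": [0.0, 0.0, 0.0],
             "s2": [3.0, 1.0, 2.0]}
        panel = make_xy_panel(x, x)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = dynamical_correlation(panel, "x", "y",
                                        remove_mean_trend=False)
        assert len(res.subject_rhos) == 2

    def test_truncation_to_shared_indices(self):
        rng = np.random.default_rng(35)
        x = {"s0": rng.normal(size=10), "s1": rng.normal(size=6),
             "s2": rng.normal(size=8)}
        panel = make_xy_panel(x, x)
        res = dynamical_correlation(panel, "x", "y")
        # shortest curve fixes the common grid; X == Y still gives rho = 1
        assert res.rho == pytest.approx(1.0, abs=1e-12)
        trunc = {k: v[:6] for k, v in x.items()}
        ref = dynamical_correlation(make_xy_panel(trunc, trunc), "x", "y")
        assert res.rho == pytest.approx(ref.rho, abs=1e-12)


class TestBootstrapDynCorr:
    def _correlated_panel(self, rng, n=8, t=10):
        x = {f"s{i}": rng.normal(size=t) for i in range(n)}
        y = {k: v + rng.normal(0, 0.1, t) for k, v in x.items()}
        return make_xy_panel(x, y)

    def test_fixed_seed_reproducible(self):
        panel = self._correlated_panel(np.random.default_rng(41))
        a = bootstrap_dyncorr(panel, "x", "y", n_boot=200, seed=7)
        b = bootstrap_dyncorr(panel, "x", "y", n_boot=200, seed=7)
        assert (a.ci_low, a.ci_high, a.p_value) == \
            (b.ci_low, b.ci_high, b.p_value)

    def test_correlated_curves_ci_excludes_zero(self):
        panel = self._correlated_panel(np.random.default_rng(42))
        res = bootstrap_dyncorr(panel, "x", "y", n_boot=500, seed=1)
        assert res.ci_low > 0.0
        assert res.p_value < 0.05
        assert -1.0 <= res.ci_low <= res.rho <= res.ci_high <= 1.0

    def test_independent_noise_ci_covers_zero(self):
        rng = np.random.default_rng(43)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            x = {f"s{i}": rng.normal(size=8) for i in range(8)}
            y = {f"s{i}": rng.normal(size=8) for i in range(8)}
            res = bootstrap_dyncorr(make_xy_panel(x, y), "x", "y",
                                    n_boot=99, seed=int(rng.integers(2**31)))
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered / n_rep >= 0.90

    def test_ci_narrows_with_subjects(self):
        rng = np.random.default_rng(44)
        widths = []
        for n in (10, 40):
            x = {f"s{i}": rng.normal(size=10) for i in range(n)}
            y = {k: v + rng.normal(0, 1.0, 10) for k, v in x.items()}
            res = bootstrap_dyncorr(make_xy_panel(x, y), "x", "y",
                                    n_boot=400, seed=5)
            widths.append(res.ci_high - res.ci_low)
        assert widths[1] < widths[0]

    def test_needs_five_subjects(self):
        rng = np.random.default_rng(45)
        x = {f"s{i}": rng.normal(size=6) for i in range(4)}
        with pytest.raises(ValueError):
            bootstrap_dyncorr(make_xy_panel(x, x), "x", "y")


class TestPearson:
    def test_linear_relationships(self):
        x = {"s0": [1.0, 2.0, 3.0, 4.0]}
        y_pos = {"s0": [3.0, 5.0, 7.0, 9.0]}  # y = 2x + 1
        r, _ = pearson_r(make_xy_panel(x, y_pos), "x", "y")
        assert r == pytest.approx(1.0, abs=1e-12)
        y_neg = {"s0": [-1.0, -2.0, -3.0, -4.0]}
        r, _ = pearson_r(make_xy_panel(x, y_neg), "x", "y")
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        x = {"s0": [1.0, 1.0, 1.0]}
        y = {"s0": [1.0, 2.0, 3.0]}
        with pytest.raises(ValueError):
            pearson_r(make_xy_panel(x, y), "x", "y")

    def test_leak_evt_negative_on_simulated_manikin(self, study_run):
        r, _ = pearson_r(study_run.panel, "leak", "ev_t", group="M")
        assert r < -0.4


class TestChiSquare:
    def test_hand_computed_2x2(self):
        # observed [[4,14],[7,11]]: expected from margins, sum (O-E)^2/E
        obs = np.array([[4.0, 14.0], [7.0, 11.0]])
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row @ col / obs.sum()
        expected_stat = float(((obs - exp) ** 2 / exp).sum())
        stat, p = chi_square_obstruction(4, 18, 7, 18)
        assert stat == pytest.approx(expected_stat, rel=1e-12)
        assert stat == pytest.approx(1.178, abs=0.001)
        assert 0.0 < p < 1.0

    def test_identical_proportions_zero(self):
        stat, p = chi_square_obstruction(5, 18, 5, 18)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_perfect_separation_maximal(self):
        stat, _ = chi_square_obstruction(18, 18, 0, 18)
        assert stat == pytest.approx(36.0)

    def test_equals_squared_two_proportion_z(self):
        for (a, n1, b, n2) in [(4, 18, 7, 18), (3, 12, 9, 15), (1, 9, 5, 9)]:
            p1, p2 = a / n1, b / n2
            pp = (a + b) / (n1 + n2)
            z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
            stat, _ = chi_square_obstruction(a, n1, b, n2)
            assert stat == pytest.approx(z ** 2, rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_obstruction(0, 18, 0, 18)
        with pytest.raises(ValueError):
            chi_square_obstruction(19, 18, 0, 18)


class TestStationarityScreen:
    def test_warns_on_random_walk_series(self):
        rng = np.random.default_rng(51)
        curves = {"s0": np.cumsum(rng.normal(size=60)),
                  "s1": rng.normal(size=60)}
        panel = make_panel(curves, parameter="pip")
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            res = adf_stationarity_screen(panel, "pip")
        assert len(res) == 2
        # the stationary series should typically reject the unit root
        assert res.set_index("subject_id").loc["s1", "stationary"] in (True, False)
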