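import math

import numpy as np
import pytest
from scipy import stats

from paintbench.doseresponse import (
    BMR_FACTOR,
    DoseSeries,
    HillModel,
    PolynomialModel,
    PowerModel,
    anova_prefilter,
    fit_model,
    model_mean,
    run_chemical,
    select_best,
)

PAPER_DOSES = np.array([0.0, 0.025, 0.25, 2.5, 25.0])


def make_series(mean_fn, sigma, rng, doses=PAPER_DOSES, reps=6):
    d = np.repeat(doses, reps)
    y = mean_fn(d) + rng.normal(0, sigma, d.size)
    return DoseSeries(d, y)


def grid_llf_oracle(series, n_grid=50):
    """Independent Hill-likelihood oracle: exhaustive (nu, k, n) grid with
    the intercept solved analytically, returning the best log-likelihood."""
    d, y = series.doses, series.values
    pos = d[d > 0]
    ks = np.exp(np.linspace(np.log(pos.min() / 10), np.log(pos.max() * 10), n_grid))
    ns = np.linspace(1.0, 8.0, n_grid)
    r = float(y.max() - y.min()) or 1.0
    nus = np.linspace(-2 * r, 2 * r, n_grid)
    kk, nn = np.meshgrid(ks, ns, indexing="ij")
    frac = np.where(
        d[None, None, :] > 0,
        d[None, None, :] ** nn[..., None]
        / (kk[..., None] ** nn[..., None] + d[None, None, :] ** nn[..., None]),
        0.0,
    )  # (k, n, obs)
    yc = y - y.mean()
    fc = frac - frac.mean(axis=-1, keepdims=True)
    A = float(yc @ yc)
    B = np.tensordot(fc, yc, axes=([-1], [0]))  # (k, n)
    C = (fc * fc).sum(axis=-1)
    sse = A - 2 * nus[None, None, :] * B[..., None] + nus[None, None, :] ** 2 * C[..., None]
    best_sse = float(sse.min())
    n = y.size
    sig2 = max(best_sse / n, 1e-24)
    return -0.5 * n * (math.log(2 * math.pi * sig2) + best_sse / (n * sig2))


class TestModelMean:
    @pytest.mark.parametrize(
        "family, params, d, expected",
        [
            ("hill", {"gamma": 0, "nu": 1, "k": 1, "n": 1}, 1.0, 0.5),
            ("power", {"gamma": 2, "beta": 2, "delta": 1}, 3.0, 8.0),
            ("poly", {"degree": 2, "coefs": [1, 0, 1]}, 2.0, 5.0),
            ("hill", {"gamma": 1, "nu": 4, "k": 2, "n": 2}, 0.0, 1.0),
        ],
    )
    def test_values(self, family, params, d, expected):
        assert model_mean(family, params, d) == pytest.approx(expected)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            model_mean("power", {"gamma": 0, "beta": 1, "delta": 1}, -1.0)


class TestAnovaPrefilter:
    def test_textbook_two_group_f(self):
        # groups {0,1,2} and {3,4,5}: SSB=13.5, SSW=4 -> F=13.5, p~0.0213
        series = DoseSeries(
            np.array([0, 0, 0, 1, 1, 1.0]), np.array([0, 1, 2, 3, 4, 5.0])
        )
        res = anova_prefilter(series, fc_cut=1.0)
        assert res.f_stat == pytest.approx(13.5, rel=1e-12)
        assert res.p_value == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-12)
        assert res.p_value == pytest.approx(0.0213, abs=2e-4)
        assert res.passed  # |delta mean| = 3 >= 1 and p < 0.05

    def test_identical_values_fail_without_error(self, caplog):
        series = DoseSeries(np.repeat([0, 1, 2.0], 3), np.full(9, 7.0))
        with caplog.at_level("WARNING"):
            res = anova_prefilter(series)
        assert not res.passed and math.isnan(res.f_stat)

    def test_fold_change_is_conjunctive(self):
        # strong p but |delta| = 0.9 < 1 -> fail
        rng = np.random.default_rng(0)
        d = np.repeat([0.0, 1.0], 50)
        y = np.where(d > 0, 0.9, 0.0) + rng.normal(0, 0.05, 100)
        res = anova_prefilter(DoseSeries(d, y))
        assert res.p_value < 1e-6
        assert res.max_abs_diff < 1.0 and not res.passed


class TestFitModel:
    def test_linear_poly_exact(self):
        d = np.repeat([0.0, 1, 2, 3], 2)
        res = fit_model(DoseSeries(d, 2 + 3 * d), "poly", degree=1)
        b0, b1 = res.params["coefs"]
        assert (b0, b1) == (pytest.approx(2.0), pytest.approx(3.0))
        assert res.sigma <= 1e-9  # sigma floor handles the perfect fit
        assert res.aic == pytest.approx(2 * 3 - 2 * res.llf)

    def test_poly_identifiability_guard(self):
        d = np.repeat([0.0, 1, 2], 2)
        with pytest.raises(ValueError, match="degree"):
            fit_model(DoseSeries(d, d), "poly", degree=2)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="distinct doses"):
            DoseSeries(np.repeat([0.0, 1], 3), np.zeros(6)).validate_for_fit()
        with pytest.raises(ValueError):
            fit_model(DoseSeries(np.repeat([0.0, 1], 3), np.zeros(6)), "hill")

    def test_hill_beats_grid_oracle(self):
        # ML optimum must match or exceed an exhaustive-grid likelihood
        rng = np.random.default_rng(42)
        series = make_series(
            lambda d: 5 * d**2 / (2.5**2 + d**2), 0.25, rng
        )
        res = fit_model(series, "hill", seed=1)
        assert res.llf >= grid_llf_oracle(series) - 1e-3

    def test_power_recovers_exponent(self):
        rng = np.random.default_rng(7)
        series = make_series(lambda d: 1.0 + 0.02 * d**1.5, 0.05, rng)
        res = fit_model(series, "power", seed=1)
        # the exponent is weakly identified from 4 positive doses; accept a
        # generous neighborhood of the truth
        assert res.params["delta"] == pytest.approx(1.5, abs=0.6)

    def test_power_delta_bounded_below(self):
        rng = np.random.default_rng(3)
        # sublinear truth: the delta >= 1 restriction must bind
        series = make_series(lambda d: np.sqrt(d), 0.05, rng)
        res = fit_model(series, "power", seed=1)
        assert res.params["delta"] >= 1.0


class TestBmc:
    def test_power_unit_slope_closed_form(self):
        """For a unit-slope linear power curve with sigma 1, the BMC is the
        benchmark response factor itself."""
        rng = np.random.default_rng(0)
        series = make_series(lambda d: d, 1.0, rng)
        res = fit_model(series, "power")
        res.params.update(gamma=0.0, beta=1.0, delta=1.0)
        res.sigma = 1.0
        b = res.bmc()
        assert b.bmc == pytest.approx(BMR_FACTOR, rel=1e-12)
        assert b.direction == "UP"

    def test_hill_half_bmr_amplitude_gives_k(self):
        # nu = 2 * bmr -> the BMR is reached exactly at d = k, any n
        rng = np.random.default_rng(0)
        series = make_series(lambda d: d, 0.5, rng)
        res = fit_model(series, "hill")
        for n in (1.0, 2.0, 3.7):
            res.params.update(gamma=0.0, nu=2 * BMR_FACTOR * res.sigma, k=2.5, n=n)
            assert res.bmc().bmc == pytest.approx(2.5, rel=1e-12)

    def test_hill_small_amplitude_undefined(self):
        rng = np.random.default_rng(0)
        series = make_series(lambda d: d, 1.0, rng)
        res = fit_model(series, "hill")
        res.params.update(gamma=0.0, nu=1.0 * res.sigma, k=2.5, n=2.0)
        assert math.isnan(res.bmc().bmc)

    def test_hill_k_flag_set_and_retained(self):
        rng = np.random.default_rng(5)
        series = make_series(
            lambda d: 4 * d / (0.01 + d), 0.3, rng
        )
        res = fit_model(series, "hill", seed=2)
        res.params["k"] = 0.01  # below the lowest positive dose 0.025
        b = res.bmc()
        assert b.hill_k_flag
        assert math.isfinite(b.bmc)  # flagged fits are kept, not discarded

    def test_poly_root_matches_power_closed_form(self):
        # a degree-1 polynomial is also a delta=1 power curve: the numeric
        # root-finder must agree with the closed form to 1e-9 relative
        rng = np.random.default_rng(1)
        series = make_series(lambda d: 0.5 + 0.8 * d, 0.7, rng)
        poly = fit_model(series, "poly", degree=1)
        power = fit_model(series, "power")
        b_poly = poly.bmc().bmc
        closed = BMR_FACTOR * poly.sigma / abs(poly.params["coefs"][1])
        assert b_poly == pytest.approx(closed, rel=1e-9)
        assert power.bmc().bmc == pytest.approx(closed, rel=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        series = make_series(lambda d: 5 * d / (2.5 + d), 0.3, rng)
        scaled = DoseSeries(series.doses * 10, series.values)
        for family in ("hill", "power"):
            b1 = fit_model(series, family, seed=3).bmc().bmc
            b10 = fit_model(scaled, family, seed=3).bmc().bmc
            assert b10 == pytest.approx(10 * b1, rel=1e-3)

    def test_bmc_increases_with_bmr(self):
        rng = np.random.default_rng(2)
        series = make_series(lambda d: 5 * d / (2.5 + d), 0.3, rng)
        res = fit_model(series, "hill", seed=1)
        bmcs = [res.bmc(bmr_factor=f).bmc for f in (0.5, 1.0, 1.349, 2.0)]
        assert all(a < b for a, b in zip(bmcs, bmcs[1:]))


class TestBmcl:
    def test_lower_bound_property(self):
        rng = np.random.default_rng(4)
        for fam in ("power", "hill", "poly"):
            series = make_series(lambda d: 3 * d / (2.5 + d), 0.4, rng)
            kw = {"degree": 1} if fam == "poly" else {}
            res = fit_model(series, fam, seed=1, **kw)
            b = res.bmc(compute_bmcl=True)
            if math.isfinite(b.bmc):
                assert b.bmcl <= b.bmc * (1 + 1e-9)

    def test_noiseless_gap_closes(self):
        # with an exact fit the likelihood is degenerate and the profile
        # bound collapses onto the BMC
        d = np.repeat(PAPER_DOSES, 6)
        series = DoseSeries(d, 1 + 0.5 * d)
        res = fit_model(series, "poly", degree=1)
        b = res.bmc(compute_bmcl=True)
        assert math.isfinite(b.bmcl)
        assert (b.bmc - b.bmcl) / b.bmc < 0.01

    def test_coverage_small_simulation(self):
        # one-sided 95% bound should under-cover rarely (full-size check
        # lives in the acceptance suite)
        rng = np.random.default_rng(123)
        true_bmc = BMR_FACTOR * 0.5 / 0.3
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            series = make_series(lambda d: 0.3 * d, 0.5, rng, doses=PAPER_DOSES)
            res = fit_model(series, "power", seed=1)
            b = res.bmc(compute_bmcl=True)
            if math.isfinite(b.bmcl) and b.bmcl < true_bmc:
                hits += 1
        assert hits / n_sim >= 0.8


class TestSelectBest:
    def test_aic_tie_breaks_to_simpler_family(self):
        rng = np.random.default_rng(0)
        series = make_series(lambda d: 1 + 0.3 * d, 0.3, rng)
        poly = fit_model(series, "poly", degree=1)
        power = fit_model(series, "power")
        # force an exact AIC tie
        power.aic = poly.aic
        best = select_best([power, poly])
        assert best.family == "poly"

    def test_no_converged_fits_returns_none(self):
        rng = np.random.default_rng(0)
        series = make_series(lambda d: d, 0.5, rng)
        f = fit_model(series, "poly", degree=1)
        f.converged = False
        assert select_best([f]) is None

    def test_strong_sigmoid_prefers_hill(self):
        # 8-point dose series: the screen's 4-dose design discriminates the
        # families weakly, so the consistency check uses a denser series
        rng = np.random.default_rng(6)
        dense = np.array([0.0, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
        wins = 0
        for _ in range(20):
            series = make_series(
                lambda d: 6 * d**4 / (1.0 + d**4), 1.0, rng, doses=dense
            )
            fits = [
                fit_model(series, "poly", degree=1),
                fit_model(series, "poly", degree=2),
                fit_model(series, "power", seed=1),
                fit_model(series, "hill", seed=1),
            ]
            if select_best(fits).family == "hill":
                wins += 1
        assert wins >= 12

    def test_linear_truth_keeps_degree_one(self):
        rng = np.random.default_rng(8)
        keep = 0
        n_sim = 30
        for _ in range(n_sim):
            series = make_series(lambda d: 1 + 0.2 * d, 0.5, rng)
            polys = [
                fit_model(series, "poly", degree=1),
                fit_model(series, "poly", degree=2),
            ]
            best = select_best(polys)
            if best.params["degree"] == 1:
                keep += 1
        assert keep / n_sim >= 0.8


class TestRunChemical:
    def test_constant_feature_fails_prefilter_without_fit(self, planted_plate):
        import pandas as pd

        cells, truth, design, effects = planted_plate
        from paintbench.profiles import preprocess

        prof, _ = preprocess(cells)
        prof["Cells_AreaShape_Area"] = 1.0  # constant across all wells
        tab = run_chemical(prof, "ChemA", features=["Cells_AreaShape_Area"])
        row = tab.iloc[0]
        assert not row["prefilter_pass"] and row["family"] is None

    def test_deterministic_given_seed(self, planted_plate):
        cells, *_ = planted_plate
        from paintbench.profiles import preprocess

        prof, _ = preprocess(cells)
        feats = [c for c in prof.columns if c.startswith("Nuclei_")][:5]
        a = run_chemical(prof, "ChemA", features=feats, seed=7)
        b = run_chemical(prof, "ChemA", features=feats, seed=7)
        import pandas as pd

        pd.testing.assert_frame_equal(a, b)
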