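"""Cohort generator: covariate distributions, error model, outcome shapes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orcurve import (
    ConfigurationError,
    ScenarioConfig,
    add_measurement_error,
    build_cohort,
    compute_latent_outcome,
    draw_covariates,
    read_cohort,
    round_truncate,
    transform_to_aosi,
)
from conftest import SEED, assemble


class TestDrawCovariates:
    def test_moments_recover_parameters(self):
        n = 100_000
        cov = draw_covariates(ScenarioConfig(n=n, seed=SEED))
        r = np.corrcoef(cov["x1"], cov["x2"])[0, 1]
        se_r = (1 - 0.7**2) / np.sqrt(n)
        assert abs(r - 0.7) < 4 * se_r
        assert abs(cov["x1"].var() - 1.0) < 4 * np.sqrt(2.0 / n)
        assert abs(cov["x2"].var() - 1.0) < 4 * np.sqrt(2.0 / n)
        assert abs(cov["z"].mean() - 0.5) < 4 * 0.5 / np.sqrt(n)
        males = cov[cov["z"] == 1]
        frac = males["shifted"].mean()
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / len(males))
        assert cov.loc[cov["z"] == 0, "shifted"].sum() == 0

    def test_rho_zero_gives_independent_exposures(self):
        n = 50_000
        cov = draw_covariates(ScenarioConfig(n=n, seed=SEED, rho=0.0))
        assert abs(np.corrcoef(cov["x1"], cov["x2"])[0, 1]) < 4 / np.sqrt(n)

    def test_gestational_age_mean(self):
        # E[43 - chi2(3)] minus the expected male shift: 43 - 3 - 0.5*0.05
        n = 100_000
        cov = draw_covariates(ScenarioConfig(n=n, seed=SEED))
        se = np.sqrt(6.0 / n)  # Var(chi2_3) = 6 dominates
        assert abs(cov["x_ga"].mean() - 39.975) < 4 * se

    @pytest.mark.parametrize("bad", [{"rho": 1.0}, {"rho": -1.5}, {"sigma2_w1": -0.1},
                                     {"n": 0}, {"shape": "cubic"},
                                     {"case_cutoff": 25}, {"ga_bounds": (43, 23)}])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(**bad)


class TestMeasurementError:
    def test_zero_variance_is_identity(self):
        rng = np.random.default_rng(SEED)
        x = rng.standard_normal(1000)
        assert np.array_equal(add_measurement_error(x, 0.0, rng), x)

    def test_classical_error_variance_and_independence(self):
        n = 200_000
        rng = np.random.default_rng(SEED)
        x = rng.standard_normal(n)
        w = add_measurement_error(x, 0.25, rng)
        # Var(X + eps) = 1 + sigma2
        assert abs(w.var() - 1.25) < 4 * 1.25 * np.sqrt(2.0 / n)
        # error orthogonal to the true value
        assert abs(np.corrcoef(w - x, x)[0, 1]) < 4 / np.sqrt(n)

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            add_measurement_error(np.zeros(3), -1.0, np.random.default_rng(0))


class TestRoundTruncate:
    @pytest.mark.parametrize(
        "value, expect_int, expect_keep",
        [(24.4, 24, True), (22.4, 22, False), (43.5, 44, False),
         (23.0, 23, True), (43.49, 43, True), (22.5, 23, True)],
    )
    def test_examples(self, value, expect_int, expect_keep):
        r, keep = round_truncate(np.array([value]), 23, 43)
        assert r[0] == expect_int
        assert keep[0] == expect_keep

    def test_half_integer_grid_matches_ties_away_rule(self):
        # exhaustive oracle over the half-integer grid: ties away from zero
        grid = np.arange(22.5, 44.0, 1.0)
        expected = np.array([int(v) + 1 for v in grid])  # positive values
        r, keep = round_truncate(grid, 23, 43)
        assert np.array_equal(r, expected)
        assert np.array_equal(keep, (expected >= 23) & (expected <= 43))

    def test_floor_mode_counts_completed_weeks(self):
        r, keep = round_truncate(np.array([24.9, 23.0, 22.9]), 23, 43, mode="floor")
        assert list(r) == [24, 23, 22]
        assert list(keep) == [True, True, False]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            round_truncate(np.zeros(1), 43, 23)


def _cov_frame(x1, z=0.0, x_ga=39.0):
    x1 = np.asarray(x1, dtype=float)
    return pd.DataFrame(
        {"x1": x1, "x2": np.zeros_like(x1), "z": np.full_like(x1, z),
         "x_ga": np.full_like(x1, x_ga), "shifted": np.zeros_like(x1)}
    )


class TestLatentOutcome:
    def test_linear_slope_is_beta1(self):
        cfg = ScenarioConfig(beta1=0.25)
        cov = _cov_frame([0.0, 1.0])
        y = compute_latent_outcome(cov, "linear", cfg, np.zeros(2))
        assert y[1] - y[0] == pytest.approx(0.25)

    def test_saturation_slope_ratio_is_three(self):
        cfg = ScenarioConfig(beta1=0.5, shape="saturation")
        # mean 0, sd 2 -> inflection at -2; pairs strictly below / above it
        x1 = np.array([-3.0, -2.5, 1.0, 2.0, 3.0, -0.5])
        cov = _cov_frame(x1)
        infl = x1.mean() - x1.std()
        assert -2.5 < infl < -2.0  # -3 and -2.5 below; 1, 2 above
        y = compute_latent_outcome(cov, "saturation", cfg, np.zeros(len(x1)))
        slope_below = (y[1] - y[0]) / (x1[1] - x1[0])
        slope_above = (y[3] - y[2]) / (x1[3] - x1[2])
        assert slope_below / slope_above == pytest.approx(3.0)
        assert slope_below == pytest.approx(1.5 * 0.5)

    def test_threshold_flat_below_inflection(self):
        cfg = ScenarioConfig(beta1=0.5, shape="threshold")
        x1 = np.array([-2.0, -1.5, 0.0, 1.0, 0.5, -0.5, 0.25, -0.25])
        cov = _cov_frame(x1)
        assert x1.mean() - x1.std() > -1.5  # both test points below inflection
        y = compute_latent_outcome(cov, "threshold", cfg, np.zeros(len(x1)))
        assert y[0] == y[1]  # zero slope below the inflection point

    def test_unknown_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_latent_outcome(_cov_frame([0.0]), "quadratic",
                                   ScenarioConfig(), np.zeros(1))


class TestAosiTransform:
    def test_integer_range_and_monotonicity(self, base_unit):
        cohort = assemble(base_unit, shape="linear", beta1=0.5, sigma2_w1=0.0)
        aosi = cohort.frame["aosi"]
        assert aosi.dtype.kind == "i"
        assert aosi.min() >= 0 and aosi.max() <= 18
        rho = stats.spearmanr(cohort.frame["y_latent"], aosi).statistic
        assert rho >= 0.95  # monotone map: rounding ties only, no inversions

    def test_prevalence_sane_for_weak_linear_scenario(self, base_unit):
        cohort = assemble(base_unit, shape="linear", beta1=0.15, sigma2_w1=0.0)
        prev = cohort.frame["case"].mean()
        assert 0.05 < prev < 0.5

    def test_constant_input_maps_to_constant(self):
        out = transform_to_aosi(np.full(10, 3.0), ScenarioConfig())
        assert len(np.unique(out)) == 1


class TestBuildCohort:
    def test_exact_size_and_inclusion(self):
        cfg = ScenarioConfig(n=20_000, seed=SEED)
        cohort = build_cohort(cfg)
        f = cohort.frame
        assert cohort.n == 20_000
        assert f["w_ga"].min() >= 23 and f["w_ga"].max() <= 43
        assert not f.isna().any().any()
        assert ((f["case"] == 1) == (f["aosi"] >= 7)).all()

    def test_seed_determinism(self):
        cfg = ScenarioConfig(n=5_000, seed=SEED)
        a = build_cohort(cfg).frame
        b = build_cohort(cfg).frame
        pd.testing.assert_frame_equal(a, b)
        c = build_cohort(cfg.replace(seed=SEED + 1)).frame
        assert not np.array_equal(a["x1"], c["x1"])

    def test_no_error_means_observed_equals_true(self, base_unit):
        cohort = assemble(base_unit, sigma2_w1=0.0)
        assert np.array_equal(cohort.frame["w1"], cohort.frame["x1"])

    def test_error_attenuates_correlation(self, base_unit):
        # corr(W1, X1) = 1/sqrt(1 + sigma2) under classical error
        cohort = assemble(base_unit, sigma2_w1=1.0)
        r = np.corrcoef(cohort.frame["w1"], cohort.frame["x1"])[0, 1]
        assert r == pytest.approx(1 / np.sqrt(2.0), abs=4 / np.sqrt(cohort.n))

    def test_outcome_independent_of_noncausal_exposure(self, linear_strong_unit):
        # beta2 = 0: partial correlation of Y and X2 given X1 vanishes
        f = linear_strong_unit.frame
        x1, x2, y = (f[c].to_numpy() for c in ("x1", "x2", "y_latent"))
        rx2 = x2 - np.polyval(np.polyfit(x1, x2, 1), x1)
        ry = y - np.polyval(np.polyfit(x1, y, 1), x1)
        assert abs(np.corrcoef(rx2, ry)[0, 1]) < 5 / np.sqrt(len(f))

    def test_pathological_inclusion_aborts(self):
        cfg = ScenarioConfig(n=1_000, seed=SEED, ga_bounds=(23, 24))
        with pytest.raises(RuntimeError, match="pathological"):
            build_cohort(cfg)

    def test_cohort_roundtrip(self, tmp_path):
        cohort = build_cohort(ScenarioConfig(n=2_000, seed=SEED))
        path = tmp_path / "cohort.csv.gz"
        cohort.write(path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(
            back.frame, cohort.frame, check_dtype=False
        )
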