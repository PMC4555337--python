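"""Logistic OR estimation: pattern collapsing, fits, curves, categories."""

import numpy as np
import pytest

from orcurve import (
    build_category_table,
    build_or_curve,
    collapse_to_patterns,
    dichotomize,
    fit_logistic,
    make_dichotomy_grid,
)
from conftest import SEED, assemble
from oracles import crossprod_or, make_cohort, rowlevel_logit_params


def _random_cohort(n=1000, seed=SEED):
    """Small cohort with all four covariates varying and a related outcome."""
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    w1 = x1 + 0.5 * rng.standard_normal(n)
    logit = -1.0 + 1.2 * (x1 > 0)
    case = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(np.int8)
    return make_cohort(
        x1,
        w1=w1,
        case=case,
        z=rng.integers(0, 2, n).astype(np.int8),
        w2=rng.standard_normal(n) + 0.5,
        w_ga=rng.integers(30, 43, n),
    )


class TestCollapse:
    def test_pattern_count_and_total(self):
        cohort = _random_cohort()
        cells = collapse_to_patterns(cohort, dichotomize(cohort.frame["w1"], 0.0))
        assert len(cells) <= 32  # 2^4 patterns x 2 outcomes
        assert cells["count"].sum() == cohort.n

    def test_collapsed_fit_equals_rowlevel_fit(self):
        """The collapsed weighted likelihood is the row-level likelihood:
        coefficients must agree to at least 6 decimals."""
        cohort = _random_cohort()
        exposure = dichotomize(cohort.frame["w1"], 0.0)
        fit = fit_logistic(collapse_to_patterns(cohort, exposure))
        oracle = rowlevel_logit_params(cohort.frame, exposure)
        for name in ("const", "exposure", "w2c", "z", "wgac"):
            assert fit.coefficients[name] == pytest.approx(oracle[name], abs=1e-6)

    def test_all_zero_exposure_flags_degeneracy(self):
        cohort = _random_cohort()
        cells = collapse_to_patterns(cohort, np.zeros(cohort.n, dtype=np.int8))
        fit = fit_logistic(cells)
        assert fit.separation
        assert np.isnan(fit.or1)


class TestFitLogistic:
    def test_reduces_to_crossproduct_ratio(self):
        """With constant adjusters the model is a 2x2 table: exp(c1) must
        equal the cross-product ratio (a*d)/(b*c)."""
        rng = np.random.default_rng(SEED)
        n = 4000
        x1 = rng.standard_normal(n)
        case = (rng.random(n) < np.where(x1 >= 0, 0.3, 0.15)).astype(np.int8)
        cohort = make_cohort(x1, case=case)  # z, w2c, wgac all constant
        exposure = dichotomize(x1, 0.0)
        fit = fit_logistic(collapse_to_patterns(cohort, exposure))
        assert fit.or1 == pytest.approx(crossprod_or(exposure == 1, case), rel=1e-9)

    def test_null_association_covered_by_ci(self):
        rng = np.random.default_rng(SEED)
        cohort = _random_cohort()
        case = rng.permutation(cohort.frame["case"].to_numpy())
        cohort.frame["case"] = case  # break the exposure-outcome link
        fit = fit_logistic(
            collapse_to_patterns(cohort, dichotomize(cohort.frame["w1"], 0.0))
        )
        lo, hi = fit.ci95
        assert lo < 1.0 < hi

    def test_zero_exposed_cases_flagged_missing(self):
        cohort = _random_cohort()
        w1 = cohort.frame["w1"].to_numpy()
        phi = w1[cohort.frame["case"] == 1].max() + 0.1  # no exposed case left
        fit = fit_logistic(collapse_to_patterns(cohort, dichotomize(w1, phi)))
        assert fit.separation
        assert np.isnan(fit.or1)
        assert fit.n_exposed_cases == 0

    def test_single_outcome_class_not_estimable(self):
        cohort = _random_cohort()
        cohort.frame["case"] = 0
        fit = fit_logistic(
            collapse_to_patterns(cohort, dichotomize(cohort.frame["w1"], 0.0))
        )
        assert fit.separation and not fit.converged


class TestORCurve:
    def test_default_grid_gives_61_points(self, linear_strong_unit):
        curve = build_or_curve(linear_strong_unit, make_dichotomy_grid(-3, 3, 0.1))
        assert len(curve.table) == 61
        assert curve.table["phi"].is_monotonic_increasing

    def test_no_error_curves_coincide(self, base_unit):
        cohort = assemble(base_unit, shape="linear", beta1=0.5, sigma2_w1=0.0)
        grid = make_dichotomy_grid(-2, 2, 0.5)
        cw = build_or_curve(cohort, grid, "w1").table
        cx = build_or_curve(cohort, grid, "x1").table
        assert np.allclose(cw["or1"], cx["or1"], equal_nan=True)

    def test_linear_shape_gives_u_curve(self, base_unit):
        cohort = assemble(base_unit, shape="linear", beta1=0.5, sigma2_w1=0.0)
        grid = make_dichotomy_grid(-2, 2, 2.0)  # phi in {-2, 0, 2} SD
        t = build_or_curve(cohort, grid).table.set_index("phi")["or1"]
        assert t[-2.0] > t[0.0] and t[2.0] > t[0.0]

    def test_failures_recorded_not_raised(self, linear_strong_unit):
        # +/-8 SD cutoffs empty an exposure class; the curve must continue
        grid = make_dichotomy_grid(-8, 8, 8.0)
        table = build_or_curve(linear_strong_unit, grid).table
        assert len(table) == 3
        assert table["separation"].iloc[0] and table["separation"].iloc[-1]
        assert np.isfinite(table["or1"].iloc[1])


class TestCategoryTable:
    def test_four_or_rows_per_delta(self, linear_strong_unit):
        deltas = [0.5, 1.0, 1.5]
        table = build_category_table(linear_strong_unit, deltas).table
        assert len(table) == 4 * len(deltas)
        assert set(table["category"]) == {1, 2, 4, 5}

    def test_global_null_gives_unit_ors(self, base_unit):
        cohort = assemble(base_unit, shape="linear", beta1=0.0, sigma2_w1=0.25)
        table = build_category_table(cohort, [1.0]).table
        assert np.all(np.abs(np.log(table["or"])) < 0.1)

    def test_monotone_dose_response_linear_no_error(self, base_unit):
        cohort = assemble(base_unit, shape="linear", beta1=0.5, sigma2_w1=0.0)
        t = build_category_table(cohort, [1.0]).table.set_index("category")["or"]
        assert t[5] > t[4] > 1.0 > t[2] > t[1]
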