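"""Logistic-regression odds ratios for categorized exposures.

For every cutoff ``phi`` (or five-category scheme) the model

    logit P(case = 1) = c0 + c1*W1c + c2*W2c + c3*Z + c4*Wgac

is fitted by maximum likelihood, where every predictor is dichotomous:
the categorized causal exposure ``W1c``, the non-causal exposure at its
conventional cutoff (``W2 >= 1``), male sex, and term birth
(``Wga >= 37`` weeks). ``exp(c1)`` is the odds ratio of interest.

Because all predictors are categorical, the likelihood depends on the
data only through covariate-pattern counts (at most 2^4 patterns per
outcome class for the dichotomous coding). Fits therefore run on the
collapsed count table with frequency weights, which makes sweeping 61
cutoffs over a million-row cohort cheap and is exactly equivalent to the
row-level fit.

Cutoffs at the extremes can empty a cell of the exposure-by-outcome
margin; such fits are flagged (``separation``) and their OR reported as
missing rather than as a divergent estimate, and curve construction
continues past them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .categorize import CategoryScheme, CutoffGrid, dichotomize, make_category_scheme
from .simulate import Cohort

__all__ = [
    "W2_CUTOFF",
    "GA_CUTOFF",
    "LogisticFit",
    "ORCurve",
    "CategoryORTable",
    "collapse_to_patterns",
    "fit_logistic",
    "build_or_curve",
    "build_category_table",
]

#: Conventional cutoffs for the adjustment covariates: the non-causal
#: exposure is coded exposed at >= 1, gestational age at >= 37 weeks
#: ("term"); the boundary is exposed, as for the causal exposure.
W2_CUTOFF = 1.0
GA_CUTOFF = 37

_Z975 = 1.959963984540054  # Phi^{-1}(0.975), Wald 95% CI


def _adjusters(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w2c = (frame["w2"].to_numpy() >= W2_CUTOFF).astype(np.int8)
    z = frame["z"].to_numpy().astype(np.int8)
    wgac = (frame["w_ga"].to_numpy() >= GA_CUTOFF).astype(np.int8)
    return w2c, z, wgac


def collapse_to_patterns(cohort: Cohort, exposure: np.ndarray) -> pd.DataFrame:
    """Collapse the cohort to covariate-pattern x outcome counts.

    ``exposure`` is the coded causal exposure per subject (0/1 for a
    dichotomy, 1..5 for the category scheme). Returns a table with
    columns ``exposure, w2c, z, wgac, case, count``; counts sum to n.
    """
    exposure = np.asarray(exposure)
    w2c, z, wgac = _adjusters(cohort.frame)
    case = cohort.frame["case"].to_numpy().astype(np.int8)
    n_exp = int(exposure.max()) + 1
    code = ((((exposure.astype(np.int64) * 2 + w2c) * 2 + z) * 2 + wgac) * 2) + case
    counts = np.bincount(code, minlength=n_exp * 16)
    idx = np.nonzero(counts)[0]
    return pd.DataFrame(
        {
            "exposure": idx // 16,
            "w2c": (idx // 8) % 2,
            "z": (idx // 4) % 2,
            "wgac": (idx // 2) % 2,
            "case": idx % 2,
            "count": counts[idx],
        }
    )


@dataclass
class LogisticFit:
    """One fitted logistic model on a collapsed count table.

    ``or1``/``ci95`` hold the dichotomous-exposure odds ratio (NaN when
    the exposure term was dropped for separation); for five-category
    codings ``category_or`` maps each non-reference category to
    ``(or, ci_lo, ci_hi)`` with NaNs for inestimable categories.
    """

    coefficients: pd.Series
    or1: float
    ci95: tuple[float, float]
    cell_counts: pd.DataFrame
    converged: bool
    separation: bool
    n_exposed_cases: int
    category_or: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    dropped_terms: tuple[str, ...] = ()


def _term_separated(cells: pd.DataFrame, indicator: np.ndarray) -> bool:
    """True when the indicator x outcome margin has an empty cell."""
    for v in (0, 1):
        for y in (0, 1):
            if cells.loc[(indicator == v) & (cells["case"] == y), "count"].sum() == 0:
                return True
    return False


def fit_logistic(cells: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic fit on covariate-pattern counts.

    The exposure coding is inferred from the ``exposure`` column: values
    in {0,1} give the dichotomous model, values in {1..5} the
    five-category model with category 3 as reference. Exposure terms
    whose margin with the outcome has an empty cell are dropped and
    flagged instead of being allowed to diverge; constant adjustment
    covariates are dropped silently (they carry no information).
    """
    cells = cells.reset_index(drop=True)
    y = cells["case"].to_numpy().astype(float)
    w = cells["count"].to_numpy().astype(float)
    exposure = cells["exposure"].to_numpy()
    levels = np.unique(exposure)
    binary = set(levels.tolist()) <= {0, 1}

    nan_fit = dict(
        coefficients=pd.Series(dtype=float),
        or1=float("nan"),
        ci95=(float("nan"), float("nan")),
        cell_counts=cells,
        n_exposed_cases=int(
            cells.loc[(exposure >= (1 if binary else 4)) & (cells["case"] == 1), "count"].sum()
        )
        if binary
        else 0,
    )
    # outcome must have both classes
    if len(np.unique(y[w > 0])) < 2:
        return LogisticFit(converged=False, separation=True, **nan_fit)

    design: dict[str, np.ndarray] = {}
    exposure_terms: list[str] = []
    separated_terms: list[str] = []
    if binary:
        ind = (exposure == 1).astype(float)
        if _term_separated(cells, ind):
            separated_terms.append("exposure")
        else:
            design["exposure"] = ind
            exposure_terms.append("exposure")
    else:
        for k in sorted(int(v) for v in levels):
            if k == 3:
                continue
            name = f"cat{k}"
            ind = (exposure == k).astype(float)
            if _term_separated(cells, ind):
                separated_terms.append(name)
            else:
                design[name] = ind
                exposure_terms.append(name)
    for name in ("w2c", "z", "wgac"):
        col = cells[name].to_numpy().astype(float)
        if col[w > 0].min() != col[w > 0].max():  # drop constants
            design[name] = col

    exog = pd.DataFrame({"const": np.ones(len(cells)), **design})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, exog, family=sm.families.Binomial(), freq_weights=w)
        res = model.fit(maxiter=100)
    params, bse = res.params, res.bse
    converged = bool(res.converged)
    separation = bool(separated_terms)

    def _or_ci(name: str) -> tuple[float, float, float]:
        c, s = params[name], bse[name]
        return (float(np.exp(c)), float(np.exp(c - _Z975 * s)), float(np.exp(c + _Z975 * s)))

    if binary:
        if "exposure" in exposure_terms:
            or1, lo, hi = _or_ci("exposure")
        else:
            or1, lo, hi = float("nan"), float("nan"), float("nan")
        n_exposed_cases = int(
            cells.loc[(exposure == 1) & (cells["case"] == 1), "count"].sum()
        )
        category_or: dict[int, tuple[float, float, float]] = {}
    else:
        or1, lo, hi = float("nan"), (float("nan")), float("nan")
        n_exposed_cases = 0
        category_or = {}
        for k in (1, 2, 4, 5):
            name = f"cat{k}"
            if name in exposure_terms:
                category_or[k] = _or_ci(name)
            elif k in levels or name in separated_terms:
                category_or[k] = (float("nan"),) * 3
            else:  # category empty in this cohort
                category_or[k] = (float("nan"),) * 3

    return LogisticFit(
        coefficients=params,
        or1=or1,
        ci95=(lo, hi),
        cell_counts=cells,
        converged=converged,
        separation=separation,
        n_exposed_cases=n_exposed_cases,
        category_or=category_or,
        dropped_terms=tuple(separated_terms),
    )


@dataclass(frozen=True)
class ORCurve:
    """Odds ratio versus dichotomization cutoff, one fit per grid point."""

    scenario: str
    exposure_source: str  # "w1" (mismeasured) or "x1" (error-free)
    table: pd.DataFrame  # phi, phi_raw, or1, ci_lo, ci_hi, n_exposed_cases, converged, separation


@dataclass(frozen=True)
class CategoryORTable:
    """Category odds ratios versus reference-group width ``delta``."""

    scenario: str
    exposure_source: str
    table: pd.DataFrame  # delta, category, or, ci_lo, ci_hi, estimable


def build_or_curve(
    cohort: Cohort,
    grid: CutoffGrid,
    exposure_source: str = "w1",
    scenario: str = "",
) -> ORCurve:
    """Fit the dichotomous logistic model at every cutoff of the grid.

    SD-unit grids are resolved against the empirical mean and SD of the
    dichotomized variable itself, so "mean + k SD" always refers to the
    distribution actually being cut. Per-cutoff failures (separation,
    non-convergence) are recorded in the table, never raised.
    """
    w = cohort.frame[exposure_source].to_numpy()
    raw = grid.resolve(float(w.mean()), float(w.std()))
    rows = []
    for phi, phi_raw in zip(grid.cutoffs, raw):
        fit = fit_logistic(collapse_to_patterns(cohort, dichotomize(w, phi_raw)))
        lo, hi = fit.ci95
        rows.append(
            (phi, phi_raw, fit.or1, lo, hi, fit.n_exposed_cases,
             fit.converged, fit.separation)
        )
    table = pd.DataFrame(
        rows,
        columns=["phi", "phi_raw", "or1", "ci_lo", "ci_hi",
                 "n_exposed_cases", "converged", "separation"],
    )
    return ORCurve(scenario=scenario, exposure_source=exposure_source, table=table)


def build_category_table(
    cohort: Cohort,
    delta_values,
    exposure_source: str = "w1",
    scenario: str = "",
) -> CategoryORTable:
    """Fit the five-category model for each reference-group width.

    For every ``delta`` the scheme is centered on the empirical mean of
    the exposure with widths in units of its empirical SD, and the ORs
    of categories 1, 2, 4 and 5 versus the central reference category
    are extracted — four OR rows per width. Categories emptied (or
    separated) at extreme widths are reported as missing.
    """
    from .categorize import assign_category

    w = cohort.frame[exposure_source].to_numpy()
    center, sd = float(w.mean()), float(w.std())
    rows = []
    for delta in delta_values:
        scheme = make_category_scheme(float(delta), center, sd)
        fit = fit_logistic(collapse_to_patterns(cohort, assign_category(w, scheme)))
        for k in (1, 2, 4, 5):
            or_k, lo, hi = fit.category_or.get(k, (float("nan"),) * 3)
            rows.append((float(delta), k, or_k, lo, hi, np.isfinite(or_k)))
    table = pd.DataFrame(
        rows, columns=["delta", "category", "or", "ci_lo", "ci_hi", "estimable"]
    )
    return CategoryORTable(scenario=scenario, exposure_source=exposure_source, table=table)
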