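"""Synthetic birth-cohort generator.

Generates a cohort of ``n`` children with:

* two correlated standard-normal environmental exposures (Pearson
  correlation ``rho``), of which only the first is causal;
* male sex drawn Bernoulli(``male_prob``);
* true gestational age ``43 - gamma`` weeks with ``gamma ~ chi2(3)``, a
  one-week reduction for a random ``male_shift_frac`` of males, classical
  reporting error, rounding to completed weeks and an inclusive
  ``[23, 43]``-week live-birth inclusion criterion;
* classical additive Gaussian measurement error on both exposures
  (``W = X + eps``, ``eps ~ N(0, sigma2)``);
* a latent continuous outcome under one of three exposure-response
  shapes (linear / threshold / saturation), mapped monotonically onto an
  integer severity score in ``[0, 18]`` (AOSI-like), with cases defined
  by score >= 7.

Randomness is organized as one master seed spawning named independent
substreams (covariates, male shift, each error source, outcome noise), so
changing the measurement-error variance of one observed variable never
perturbs any other draw. In particular the exposure errors are stored as
standard-normal draws scaled by ``sqrt(sigma2)`` at assembly time, which
makes cohorts with different error variances *paired*: they share the
same children and the same underlying error quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError, ScenarioConfig

__all__ = [
    "Cohort",
    "CohortBase",
    "draw_covariates",
    "add_measurement_error",
    "round_truncate",
    "compute_latent_outcome",
    "transform_to_aosi",
    "draw_base",
    "assemble_cohort",
    "build_cohort",
    "read_cohort",
]

#: Named random substreams, spawned in this fixed order from the master seed.
_STREAMS = ("covariates", "sex", "male_shift", "eps1", "eps2", "eps_ga", "eps_y")

#: Columns of a written cohort file, in deterministic order.
COHORT_COLUMNS = [
    "x1", "x2", "z", "x_ga", "shifted",
    "w1", "w2", "w_ga", "y_latent", "aosi", "case",
]

#: Fields of ScenarioConfig that determine the shared base draws
#: (everything except the outcome model and the W1 error variance).
_BASE_FIELDS = (
    "seed", "n", "rho", "male_prob", "male_shift_frac",
    "sigma2_ga", "ga_bounds", "ga_round_mode",
)


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (unlike banker's)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


# ---------------------------------------------------------------------------
# elementary operations


def _draw_covariates_batch(
    m: int, config: ScenarioConfig, rngs: dict[str, np.random.Generator]
) -> pd.DataFrame:
    """Draw ``m`` true-covariate records from the named substreams."""
    rho = config.rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    x = rngs["covariates"].multivariate_normal(
        np.zeros(2), cov, size=m, method="cholesky"
    )
    z = (rngs["sex"].random(m) < config.male_prob).astype(np.int8)
    gamma = rngs["covariates"].chisquare(3, size=m)
    shifted = ((rngs["male_shift"].random(m) < config.male_shift_frac) & (z == 1))
    x_ga = 43.0 - gamma - shifted.astype(float)
    return pd.DataFrame(
        {
            "x1": x[:, 0],
            "x2": x[:, 1],
            "z": z,
            "x_ga": x_ga,
            "shifted": shifted.astype(np.int8),
        }
    )


def draw_covariates(
    config: ScenarioConfig, size: int | None = None
) -> pd.DataFrame:
    """Draw the true covariate table (before any inclusion criterion).

    Returns a DataFrame with columns ``x1, x2, z, x_ga, shifted``:
    jointly Gaussian exposures with standard margins and correlation
    ``config.rho``, Bernoulli sex, and gestational age ``43 - chi2(3)``
    minus one week for the randomly shifted subset of males.
    """
    return _draw_covariates_batch(size or config.n, config, _spawn_rngs(config.seed))


def add_measurement_error(
    values: np.ndarray, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Contaminate ``values`` with classical error: ``values + N(0, sigma2)``.

    The error draws are independent of the input and of every other
    stream; with ``sigma2 == 0`` the output equals the input exactly.
    """
    if sigma2 < 0:
        raise ConfigurationError("measurement-error variance must be non-negative")
    values = np.asarray(values, dtype=float)
    if sigma2 == 0:
        return values.copy()
    return values + np.sqrt(sigma2) * rng.standard_normal(values.shape)


def round_truncate(
    values: np.ndarray, lo: int, hi: int, mode: str = "half-away"
) -> tuple[np.ndarray, np.ndarray]:
    """Round to integers and mark values inside ``[lo, hi]`` for retention.

    ``mode="half-away"`` rounds ties away from zero; ``mode="floor"``
    truncates downward (completed weeks). Returns ``(rounded, keep)``
    where ``keep`` flags rounded values within the inclusive bounds;
    callers decide whether to drop or clamp the rest.
    """
    if lo >= hi:
        raise ConfigurationError("round_truncate requires lo < hi")
    values = np.asarray(values, dtype=float)
    if mode == "half-away":
        r = _round_half_away(values)
    elif mode == "floor":
        r = np.floor(values)
    else:
        raise ConfigurationError(f"unknown rounding mode {mode!r}")
    r = r.astype(np.int64)
    keep = (r >= lo) & (r <= hi)
    return r, keep


def compute_latent_outcome(
    cov: pd.DataFrame,
    shape: str,
    config: ScenarioConfig,
    eps_y: np.ndarray,
) -> np.ndarray:
    """Evaluate the latent outcome under the requested response shape.

    The common part ``beta2*x2 + beta3*z + beta4*x_ga + eps_y`` is shared;
    the contribution of the causal exposure ``x1`` is piecewise around the
    inflection point ``mean(x1) - sd(x1)`` computed from the realized
    cohort:

    * ``linear``:     ``beta1 * x1`` everywhere;
    * ``threshold``:  ``0`` below the inflection, ``1.5 * beta1 * x1`` at
      or above it;
    * ``saturation``: ``1.5 * beta1 * x1`` below, ``0.5 * beta1 * x1`` at
      or above it (slope ratio 3:1).

    The branch multipliers apply to ``beta1 * x1`` itself, so the latent
    outcome is deliberately discontinuous at the inflection point.
    """
    x1 = cov["x1"].to_numpy()
    base = (
        config.beta2 * cov["x2"].to_numpy()
        + config.beta3 * cov["z"].to_numpy()
        + config.beta4 * cov["x_ga"].to_numpy()
        + np.asarray(eps_y, dtype=float)
    )
    if shape == "linear":
        return config.beta1 * x1 + base
    inflection = x1.mean() - x1.std()
    below = x1 < inflection
    if shape == "threshold":
        slope_lo, slope_hi = 0.0, 1.5
    elif shape == "saturation":
        slope_lo, slope_hi = 1.5, 0.5
    else:
        raise ConfigurationError(f"unknown outcome shape {shape!r}")
    return np.where(below, slope_lo, slope_hi) * config.beta1 * x1 + base


def inflection_point(x1: np.ndarray) -> float:
    """Inflection point of the piecewise models: ``mean(x1) - sd(x1)``."""
    x1 = np.asarray(x1, dtype=float)
    return float(x1.mean() - x1.std())


def transform_to_aosi(y: np.ndarray, config: ScenarioConfig) -> np.ndarray:
    """Map the latent outcome onto the integer severity scale.

    A strictly monotone lognormal-style map: ``y`` is standardized, sent
    through ``exp(mu_log + sigma_log * y_std)``, rounded to the nearest
    integer (ties away from zero) and clamped into ``aosi_bounds``.
    Monotonicity means rounding can create ties but never inversions.
    Clamping (rather than exclusion) keeps the cohort size fixed.
    """
    y = np.asarray(y, dtype=float)
    sd = y.std()
    y_std = (y - y.mean()) / sd if sd > 0 else np.zeros_like(y)
    raw = np.exp(config.aosi_mu_log + config.aosi_sigma_log * y_std)
    lo, hi = config.aosi_bounds
    return np.clip(_round_half_away(raw), lo, hi).astype(np.int64)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass(frozen=True)
class CohortBase:
    """Shared draws of one cohort: covariates, inclusion, error quantiles.

    Holds everything that does not depend on the outcome shape, the
    effect size or the W1 error variance, so one base can be assembled
    into every scenario of the study grid with fully paired randomness.
    ``e1_std``/``e2_std`` are standard-normal error quantiles scaled by
    ``sqrt(sigma2)`` at assembly; ``eps_y`` is the N(0,1) outcome noise.
    """

    frame: pd.DataFrame  # x1 x2 z x_ga shifted w_ga e1_std e2_std eps_y
    config: ScenarioConfig

    @property
    def n(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class Cohort:
    """A fully assembled scenario cohort: one row per retained child."""

    frame: pd.DataFrame  # COHORT_COLUMNS
    config: ScenarioConfig

    @property
    def n(self) -> int:
        return len(self.frame)

    def write(self, path: str | Path) -> None:
        """Write the cohort as gzip CSV with a deterministic column order."""
        self.frame.to_csv(path, index=False, compression="infer")


def read_cohort(path: str | Path, config: ScenarioConfig | None = None) -> Cohort:
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks columns {missing}")
    return Cohort(frame[COHORT_COLUMNS], config or ScenarioConfig(n=len(frame)))


def draw_base(config: ScenarioConfig) -> CohortBase:
    """Draw covariates and error quantiles until exactly ``n`` children
    satisfy the gestational-age inclusion criterion.

    Children whose observed (rounded) gestational age falls outside
    ``ga_bounds`` are discarded and fresh children drawn from the same
    streams, so the retained cohort has exactly ``config.n`` rows.
    Aborts if the first batch retains fewer than 10% of draws.
    """
    rngs = _spawn_rngs(config.seed)
    lo, hi = config.ga_bounds
    sd_ga = np.sqrt(config.sigma2_ga)
    parts: list[pd.DataFrame] = []
    kept = 0
    first = True
    while kept < config.n:
        m = max(int((config.n - kept) * 1.05) + 100, 1000)
        batch = _draw_covariates_batch(m, config, rngs)
        eps_ga = sd_ga * rngs["eps_ga"].standard_normal(m)
        w_ga, keep = round_truncate(
            batch["x_ga"].to_numpy() + eps_ga, lo, hi, config.ga_round_mode
        )
        batch["w_ga"] = w_ga
        batch["e1_std"] = rngs["eps1"].standard_normal(m)
        batch["e2_std"] = rngs["eps2"].standard_normal(m)
        batch["eps_y"] = rngs["eps_y"].standard_normal(m)
        if first and keep.mean() < 0.10:
            raise RuntimeError(
                f"pathological configuration: only {keep.mean():.1%} of draws "
                f"fall within gestational-age bounds {config.ga_bounds}"
            )
        first = False
        batch = batch.loc[keep]
        parts.append(batch)
        kept += len(batch)
    frame = pd.concat(parts, ignore_index=True).iloc[: config.n].reset_index(drop=True)
    return CohortBase(frame=frame, config=config)


def assemble_cohort(base: CohortBase, config: ScenarioConfig) -> Cohort:
    """Assemble a scenario cohort from shared base draws.

    Applies the W1/W2 error variances, evaluates the latent outcome under
    ``config.shape`` and derives the severity score and case status. The
    base must have been drawn under the same structural parameters.
    """
    for name in _BASE_FIELDS:
        if getattr(base.config, name) != getattr(config, name):
            raise ConfigurationError(
                f"base/config mismatch on {name}: "
                f"{getattr(base.config, name)!r} != {getattr(config, name)!r}"
            )
    f = base.frame
    cov = f[["x1", "x2", "z", "x_ga", "shifted"]]
    w1 = f["x1"].to_numpy() + np.sqrt(config.sigma2_w1) * f["e1_std"].to_numpy()
    w2 = f["x2"].to_numpy() + np.sqrt(config.sigma2_w2) * f["e2_std"].to_numpy()
    y = compute_latent_outcome(cov, config.shape, config, f["eps_y"].to_numpy())
    aosi = transform_to_aosi(y, config)
    case = (aosi >= config.case_cutoff).astype(np.int8)
    frame = pd.DataFrame(
        {
            "x1": f["x1"].to_numpy(),
            "x2": f["x2"].to_numpy(),
            "z": f["z"].to_numpy(),
            "x_ga": f["x_ga"].to_numpy(),
            "shifted": f["shifted"].to_numpy(),
            "w1": w1,
            "w2": w2,
            "w_ga": f["w_ga"].to_numpy(),
            "y_latent": y,
            "aosi": aosi,
            "case": case,
        }
    )
    return Cohort(frame=frame, config=config)


def build_cohort(config: ScenarioConfig) -> Cohort:
    """Draw and assemble a complete cohort for one scenario."""
    return assemble_cohort(draw_base(config), config)
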