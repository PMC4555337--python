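"""Scenario and study-grid configuration.

A :class:`ScenarioConfig` holds every knob of one simulated cohort: the
shape of the latent exposure-response model, the regression coefficients,
the measurement-error variances, the gestational-age inclusion window and
the severity-score (AOSI) transform. A :class:`StudyGrid` is the cartesian
product of scenario axes the full study sweeps over.

Configs can be read from and written to YAML/JSON files whose keys mirror
the dataclass field names.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

SHAPES = ("linear", "threshold", "saturation")

#: Default measurement-error variances for the causal exposure; 0 is the
#: no-error reference, the rest span good to poor precision.
DEFAULT_SIGMA2 = (0.0, 0.0625, 0.25, 1.0)

#: Default effect sizes: weak, moderate, strong.
DEFAULT_BETA1 = (0.15, 0.25, 0.5)


class ConfigurationError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


@dataclass(frozen=True)
class ScenarioConfig:
    """All simulation parameters for one synthetic birth cohort.

    Parameters
    ----------
    shape
        Latent exposure-response model: ``"linear"``, ``"threshold"``
        (zero slope below the inflection point, 1.5x above) or
        ``"saturation"`` (1.5x slope below, 0.5x above).
    beta1, beta2, beta3, beta4
        Coefficients of the latent outcome on the causal exposure X1, the
        non-causal exposure X2, male sex Z, and gestational age (weeks).
    sigma2_w1, sigma2_w2, sigma2_ga
        Classical measurement-error variances of the observed exposures
        W1, W2 and of continuous gestational age before rounding to
        completed weeks. ``sigma2_ga`` defaults to (1/7)^2, a one-day
        reporting error.
    rho
        Pearson correlation of the two standard-normal true exposures.
    n
        Cohort size after the gestational-age inclusion criterion.
    male_prob, male_shift_frac
        P(male) and the fraction of males whose gestational age is
        reduced by one week.
    ga_bounds, aosi_bounds
        Inclusive integer bounds for observed gestational age (weeks) and
        for the severity score.
    case_cutoff
        Minimum severity score defining a case.
    aosi_mu_log, aosi_sigma_log
        Log-scale location and spread of the monotone lognormal map from
        the standardized latent outcome to the severity score.
    seed
        Master seed; every random stream is derived from it.
    """

    shape: str = "linear"
    beta1: float = 0.15
    beta2: float = 0.0
    beta3: float = 1.0
    beta4: float = 0.1
    sigma2_w1: float = 0.25
    sigma2_w2: float = 0.25
    sigma2_ga: float = (1.0 / 7.0) ** 2
    rho: float = 0.7
    n: int = 1_000_000
    male_prob: float = 0.5
    male_shift_frac: float = 0.05
    ga_bounds: tuple[int, int] = (23, 43)
    aosi_bounds: tuple[int, int] = (0, 18)
    case_cutoff: int = 7
    aosi_mu_log: float = 1.3
    aosi_sigma_log: float = 0.6
    ga_round_mode: str = "half-away"  # or "floor" for completed weeks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ConfigurationError(
                f"unknown shape {self.shape!r}; expected one of {SHAPES}"
            )
        for name in ("sigma2_w1", "sigma2_w2", "sigma2_ga"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not -1 < self.rho < 1:
            raise ConfigurationError("rho must lie in (-1, 1)")
        if self.n < 1:
            raise ConfigurationError("n must be a positive integer")
        if not 0 <= self.male_prob <= 1:
            raise ConfigurationError("male_prob must lie in [0, 1]")
        if not 0 <= self.male_shift_frac <= 1:
            raise ConfigurationError("male_shift_frac must lie in [0, 1]")
        if self.ga_bounds[0] >= self.ga_bounds[1]:
            raise ConfigurationError("ga_bounds must satisfy lo < hi")
        if not self.aosi_bounds[0] <= self.case_cutoff <= self.aosi_bounds[1]:
            raise ConfigurationError("case_cutoff must lie within aosi_bounds")
        if self.ga_round_mode not in ("half-away", "floor"):
            raise ConfigurationError("ga_round_mode must be 'half-away' or 'floor'")
        # tuple-ify list input from YAML
        object.__setattr__(self, "ga_bounds", tuple(self.ga_bounds))
        object.__setattr__(self, "aosi_bounds", tuple(self.aosi_bounds))

    def replace(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ga_bounds"] = list(self.ga_bounds)
        d["aosi_bounds"] = list(self.aosi_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a config from a YAML or JSON file."""
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class StudyGrid:
    """Axes of the full scenario sweep: shapes x effect sizes x error levels.

    ``sigma2_values`` includes 0 as the no-error reference, so the default
    grid holds 3 x 3 x 4 = 36 scenarios.
    """

    shapes: tuple[str, ...] = SHAPES
    beta1_values: tuple[float, ...] = DEFAULT_BETA1
    sigma2_values: tuple[float, ...] = DEFAULT_SIGMA2
    grid_lo: float = -3.0
    grid_hi: float = 3.0
    grid_step: float = 0.1
    delta_values: tuple[float, ...] = tuple(
        round(0.5 + 0.1 * k, 10) for k in range(11)
    )
    n: int = 1_000_000
    master_seed: int = 0
    base: ScenarioConfig = field(default_factory=ScenarioConfig)

    def __post_init__(self) -> None:
        for name in ("shapes", "beta1_values", "sigma2_values", "delta_values"):
            vals = tuple(getattr(self, name))
            if not vals:
                raise ConfigurationError(f"{name} must be nonempty")
            object.__setattr__(self, name, vals)
        for s in self.shapes:
            if s not in SHAPES:
                raise ConfigurationError(f"unknown shape {s!r}")

    def scenarios(self):
        """Yield (shape, beta1, sigma2, ScenarioConfig) over the grid."""
        for shape in self.shapes:
            for beta1 in self.beta1_values:
                for sigma2 in self.sigma2_values:
                    yield shape, beta1, sigma2, self.base.replace(
                        shape=shape,
                        beta1=beta1,
                        sigma2_w1=sigma2,
                        n=self.n,
                        seed=self.master_seed,
                    )

    @property
    def n_scenarios(self) -> int:
        return len(self.shapes) * len(self.beta1_values) * len(self.sigma2_values)


def scenario_id(shape: str, beta1: float, sigma2: float) -> str:
    """Stable identifier string for one (shape, effect size, error) cell."""
    return f"{shape}_b{beta1:g}_s{sigma2:g}"
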