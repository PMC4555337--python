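"""Cutoff grids and exposure categorization.

Two coding schemes for a continuous exposure:

* **Dichotomy** at a single cutoff ``phi``: exposed iff value >= phi
  (the boundary belongs to the exposed group; the unexposed group is the
  reference). The default study grid sweeps phi over mean +/- 3 SD in
  steps of 0.1 SD — 61 cutoffs.
* **Five categories** from four cutoffs ``phi_1 < phi_2 < phi_3 < phi_4``
  placed symmetrically about the cohort mean: the middle three groups
  have equal width ``delta`` (in SD units) and the reference is group 3,
  ``[phi_2, phi_3)``, centered on the mean; groups 1 and 5 are the
  unbounded tails. All intervals are half-open ``[phi_k, phi_{k+1})``,
  matching the dichotomy's >=-is-exposed convention.

Grids are built from integer indices (``lo + k*step``) rather than
cumulative addition, so endpoints are exact and the default grid is
symmetric about zero up to floating-point representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError

__all__ = [
    "CutoffGrid",
    "CategoryScheme",
    "make_dichotomy_grid",
    "dichotomize",
    "make_category_scheme",
    "assign_category",
]


@dataclass(frozen=True)
class CutoffGrid:
    """An ordered vector of dichotomization cutoffs.

    ``scale`` records whether the values are standard-deviation offsets
    from the cohort mean (``"sd-units"``, the default study convention)
    or raw values of the observed exposure (``"raw"``).
    """

    cutoffs: np.ndarray
    scale: str = "sd-units"

    def __post_init__(self) -> None:
        c = np.asarray(self.cutoffs, dtype=float)
        if c.ndim != 1 or len(c) == 0:
            raise ConfigurationError("cutoff grid must be a nonempty 1-d vector")
        if len(c) > 1 and not np.all(np.diff(c) > 0):
            raise ConfigurationError("cutoffs must be strictly increasing")
        if self.scale not in ("sd-units", "raw"):
            raise ConfigurationError("scale must be 'sd-units' or 'raw'")
        object.__setattr__(self, "cutoffs", c)

    def __len__(self) -> int:
        return len(self.cutoffs)

    def resolve(self, center: float, sd: float) -> np.ndarray:
        """Raw-scale cutoff values: ``center + k*sd`` for sd-unit grids."""
        if self.scale == "raw":
            return self.cutoffs.copy()
        return center + self.cutoffs * sd


@dataclass(frozen=True)
class CategoryScheme:
    """Four cutoffs defining five exposure categories.

    ``phi = center + sd * (-1.5, -0.5, +0.5, +1.5) * delta``, so groups
    2, 3 and 4 all have width ``delta * sd`` and the reference group 3 is
    centered on ``center`` (the cohort mean of the observed exposure).
    """

    delta: float
    phi: np.ndarray
    reference: int = 3

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.shape != (4,) or not np.all(np.diff(phi) > 0):
            raise ConfigurationError("scheme needs 4 strictly increasing cutoffs")
        object.__setattr__(self, "phi", phi)


def make_dichotomy_grid(
    lo: float, hi: float, step: float, scale: str = "sd-units"
) -> CutoffGrid:
    """Inclusive arithmetic cutoff grid from ``lo`` to ``hi``.

    Length is ``round((hi-lo)/step) + 1``; the default (-3, 3, 0.1)
    yields 61 cutoffs. A zero-width range degenerates to the single
    cutoff ``{lo}``.
    """
    if step <= 0:
        raise ConfigurationError("grid step must be positive")
    if lo > hi:
        raise ConfigurationError("grid requires lo <= hi")
    k = int(round((hi - lo) / step))
    return CutoffGrid(lo + step * np.arange(k + 1), scale=scale)


def dichotomize(w: np.ndarray, phi: float) -> np.ndarray:
    """Binary exposure indicator: 1 iff ``w >= phi``."""
    return (np.asarray(w, dtype=float) >= phi).astype(np.int8)


def make_category_scheme(delta: float, center: float, sd: float) -> CategoryScheme:
    """Build the symmetric five-category scheme for reference width ``delta``."""
    if delta <= 0:
        raise ConfigurationError("reference-group width delta must be positive")
    if sd <= 0:
        raise ConfigurationError("sd must be positive")
    offsets = np.array([-1.5, -0.5, 0.5, 1.5])
    return CategoryScheme(delta=delta, phi=center + sd * delta * offsets)


def assign_category(w: np.ndarray, scheme: CategoryScheme) -> np.ndarray:
    """Assign each value to a category in ``{1..5}``.

    Intervals are half-open on the right: category 1 is ``(-inf, phi_1)``,
    category k (2..4) is ``[phi_{k-1}, phi_k)`` and category 5 is
    ``[phi_4, inf)``. Every value receives exactly one category.
    """
    w = np.asarray(w, dtype=float)
    return (np.searchsorted(scheme.phi, w, side="right") + 1).astype(np.int8)
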