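"""Misclassification created by dichotomizing a mismeasured exposure.

True exposure status at cutoff ``phi`` is the error-free variable
dichotomized (``X1 >= phi``); observed status is the mismeasured variable
dichotomized at the same cutoff (``W1 >= phi``). Then

    sensitivity = #(exposed by X1 and by W1) / #(exposed by X1)
    specificity = #(unexposed by X1 and by W1) / #(unexposed by X1)

computed within a stratum: cases, controls, or everyone. Although the
error in W1 is non-differential, categorization makes the resulting
binary misclassification differential whenever the exposure truly
affects the outcome — sensitivity runs higher among cases and
specificity higher among controls.

Undefined ratios (an empty truth class, e.g. no truly exposed subjects
below an extreme cutoff) are reported as NaN rather than 0 or 1, so the
instability of the extremes stays visible.

ROC curves treat the continuous W1 as a classifier of the true exposure
status fixed at one named cutoff: each sweep threshold ``t`` contributes
the point ``(1 - specificity(t), sensitivity(t))``, and the area under
the resulting polyline (trapezoidal rule) summarizes how well the
mismeasured exposure recovers the true dichotomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categorize import CutoffGrid
from .simulate import Cohort

__all__ = [
    "GROUPS",
    "MisclassRow",
    "ROCCurve",
    "sens_spec",
    "sens_spec_curve",
    "roc_points",
]

GROUPS = ("cases", "controls", "all")


@dataclass(frozen=True)
class MisclassRow:
    phi: float
    group: str
    sensitivity: float  # NaN when no truly exposed subjects in the stratum
    specificity: float  # NaN when no truly unexposed subjects
    n_true_exposed: int
    n_true_unexposed: int


@dataclass(frozen=True)
class ROCCurve:
    phi_true: float
    points: pd.DataFrame  # threshold, fpr, tpr
    auc: float


def _stratum_mask(cohort: Cohort, group: str) -> np.ndarray:
    case = cohort.frame["case"].to_numpy().astype(bool)
    if group == "cases":
        return case
    if group == "controls":
        return ~case
    if group == "all":
        return np.ones(len(case), dtype=bool)
    raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")


def _sens_spec_arrays(
    truth: np.ndarray, observed: np.ndarray
) -> tuple[float, float, int, int]:
    n_exp = int(truth.sum())
    n_unexp = int((~truth).sum())
    sens = float(observed[truth].sum() / n_exp) if n_exp else float("nan")
    spec = float((~observed[~truth]).sum() / n_unexp) if n_unexp else float("nan")
    return sens, spec, n_exp, n_unexp


def sens_spec(cohort: Cohort, phi: float, group: str = "all") -> MisclassRow:
    """Sensitivity and specificity of observed exposure status at ``phi``.

    ``phi`` is on the raw scale of the exposure. Truth is ``x1 >= phi``,
    the classification under scrutiny is ``w1 >= phi``, both restricted
    to the requested stratum.
    """
    mask = _stratum_mask(cohort, group)
    truth = cohort.frame["x1"].to_numpy()[mask] >= phi
    observed = cohort.frame["w1"].to_numpy()[mask] >= phi
    sens, spec, n_exp, n_unexp = _sens_spec_arrays(truth, observed)
    return MisclassRow(float(phi), group, sens, spec, n_exp, n_unexp)


def sens_spec_curve(cohort: Cohort, grid: CutoffGrid) -> pd.DataFrame:
    """Sensitivity/specificity for every (cutoff, stratum) combination.

    SD-unit grids are resolved against the empirical mean/SD of the
    error-free exposure, which defines truth. Returns one row per
    ``(phi, group)`` — 61 cutoffs give 183 rows.
    """
    x1 = cohort.frame["x1"].to_numpy()
    w1 = cohort.frame["w1"].to_numpy()
    raw = grid.resolve(float(x1.mean()), float(x1.std()))
    rows = []
    for group in GROUPS:
        mask = _stratum_mask(cohort, group)
        xs, ws = x1[mask], w1[mask]
        for phi, phi_raw in zip(grid.cutoffs, raw):
            sens, spec, n_exp, n_unexp = _sens_spec_arrays(xs >= phi_raw, ws >= phi_raw)
            rows.append((float(phi), float(phi_raw), group, sens, spec, n_exp, n_unexp))
    return pd.DataFrame(
        rows,
        columns=["phi", "phi_raw", "group", "sensitivity", "specificity",
                 "n_true_exposed", "n_true_unexposed"],
    )


def roc_points(
    cohort: Cohort, phi_true: float, thresholds: np.ndarray
) -> ROCCurve:
    """ROC curve of the mismeasured exposure against one true dichotomy.

    Truth is fixed at ``x1 >= phi_true`` (raw scale); each threshold
    ``t`` dichotomizes ``w1`` and contributes ``(1 - specificity,
    sensitivity)``. Points are ordered for plotting (decreasing
    threshold), the polyline is closed at (0,0) and (1,1), and the
    trapezoidal area under it is attached. A degenerate truth (all one
    class) yields an empty curve with NaN area.
    """
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    truth = cohort.frame["x1"].to_numpy() >= phi_true
    w1 = cohort.frame["w1"].to_numpy()
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        empty = pd.DataFrame(columns=["threshold", "fpr", "tpr"])
        return ROCCurve(float(phi_true), empty, float("nan"))
    rows = []
    for t in thresholds[::-1]:  # high threshold -> near (0,0)
        pred = w1 >= t
        tpr = float(pred[truth].sum() / n_pos)
        fpr = float(pred[~truth].sum() / n_neg)
        rows.append((float(t), fpr, tpr))
    points = pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])
    fpr = np.concatenate(([0.0], points["fpr"].to_numpy(), [1.0]))
    tpr = np.concatenate(([0.0], points["tpr"].to_numpy(), [1.0]))
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(float(phi_true), points, auc)
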