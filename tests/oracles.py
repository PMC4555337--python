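"""Independent oracles used by the test suite.

Each oracle recomputes an expected value by a route disjoint from the
implementation it checks: closed forms, bivariate-normal quadrature, and
row-level model fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from orcurve.simulate import Cohort
from orcurve.config import ScenarioConfig


def make_cohort(
    x1, w1=None, case=None, z=None, w2=None, w_ga=None, **cfg
) -> Cohort:
    """Assemble a hand-specified cohort frame for toy examples."""
    x1 = np.asarray(x1, dtype=float)
    n = len(x1)
    frame = pd.DataFrame(
        {
            "x1": x1,
            "x2": np.zeros(n),
            "z": np.zeros(n, dtype=np.int8) if z is None else np.asarray(z),
            "x_ga": np.full(n, 39.0),
            "shifted": np.zeros(n, dtype=np.int8),
            "w1": x1 if w1 is None else np.asarray(w1, dtype=float),
            "w2": np.zeros(n) if w2 is None else np.asarray(w2, dtype=float),
            "w_ga": np.full(n, 39) if w_ga is None else np.asarray(w_ga),
            "y_latent": np.zeros(n),
            "aosi": np.zeros(n, dtype=np.int64),
            "case": np.zeros(n, dtype=np.int8) if case is None else np.asarray(case),
        }
    )
    return Cohort(frame=frame, config=ScenarioConfig(n=n, **cfg))


def upper_orthant(a: float, b: float, corr: float) -> float:
    """P(U >= a, V >= b) for standard bivariate normal with correlation corr."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, corr], [corr, 1.0]])
    return 1.0 - stats.norm.cdf(a) - stats.norm.cdf(b) + float(mvn.cdf([a, b]))


def sens_oracle(phi: float, sigma2: float) -> float:
    """P(W >= phi | X >= phi) for X ~ N(0,1), W = X + N(0, sigma2).

    (X, W/sqrt(1+sigma2)) is standard bivariate normal with correlation
    1/sqrt(1+sigma2); integrate its upper orthant.
    """
    s = np.sqrt(1.0 + sigma2)
    return upper_orthant(phi, phi / s, 1.0 / s) / stats.norm.sf(phi)


def spec_oracle(phi: float, sigma2: float) -> float:
    """P(W < phi | X < phi); by symmetry the upper orthant at (-phi, -phi)."""
    s = np.sqrt(1.0 + sigma2)
    return upper_orthant(-phi, -phi / s, 1.0 / s) / stats.norm.cdf(phi)


def roc_oracle_points(phi_true: float, sigma2: float, thresholds) -> pd.DataFrame:
    """Quadrature (fpr, tpr) at each sweep threshold for truth X >= phi_true."""
    s = np.sqrt(1.0 + sigma2)
    p_pos = stats.norm.sf(phi_true)
    rows = []
    for t in sorted(thresholds, reverse=True):
        joint = upper_orthant(phi_true, t / s, 1.0 / s)
        tpr = joint / p_pos
        fpr = (stats.norm.sf(t / s) - joint) / (1.0 - p_pos)
        rows.append((t, fpr, tpr))
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])


def trapezoid_auc(points: pd.DataFrame) -> float:
    fpr = np.concatenate(([0.0], points["fpr"].to_numpy(), [1.0]))
    tpr = np.concatenate(([0.0], points["tpr"].to_numpy(), [1.0]))
    return float(np.trapezoid(tpr, fpr))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of an empirical AUC (Hanley & McNeil 1982)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(var))


def crossprod_or(truth_exposed, case) -> float:
    """2x2 cross-product odds ratio (a*d)/(b*c)."""
    e = np.asarray(truth_exposed).astype(bool)
    y = np.asarray(case).astype(bool)
    a = np.sum(e & y)
    b = np.sum(~e & y)
    c = np.sum(e & ~y)
    d = np.sum(~e & ~y)
    return (a * d) / (b * c)


def rowlevel_logit_params(frame: pd.DataFrame, exposure) -> pd.Series:
    """Row-level maximum-likelihood logistic fit (independent of the
    collapsed-count implementation path)."""
    import statsmodels.api as sm

    exog = pd.DataFrame(
        {
            "const": 1.0,
            "exposure": np.asarray(exposure, dtype=float),
            "w2c": (frame["w2"].to_numpy() >= 1.0).astype(float),
            "z": frame["z"].to_numpy().astype(float),
            "wgac": (frame["w_ga"].to_numpy() >= 37).astype(float),
        }
    )
    res = sm.Logit(frame["case"].to_numpy().astype(float), exog).fit(disp=False)
    return res.params
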