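"""Full-study orchestration: sweep the scenario grid and persist results.

A study is the cartesian product of exposure-response shapes, effect
sizes and measurement-error variances (default 3 x 3 x 4 = 36 scenarios,
with variance 0 serving as the no-error reference). Covariate and noise
draws are shared across the whole grid — every scenario contains the
same children, with the same error quantiles scaled to the scenario's
variance — so comparisons across error levels are paired.

Products, written as long-format CSVs keyed by scenario identifiers:

* ``or_curves.csv``      — OR vs dichotomization cutoff, per error level,
  plus one error-free (X1-based) reference curve per (shape, effect);
* ``category_or.csv``    — category ORs vs reference-group width;
* ``sens_spec.csv``      — sensitivity/specificity vs cutoff by stratum;
* ``roc.csv``            — ROC points for selected true-exposure cutoffs;
* ``manifest.json``      — config, seeds and library versions, sufficient
  to regenerate every table bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .categorize import make_dichotomy_grid
from .config import ScenarioConfig, StudyGrid, scenario_id
from .logit import build_category_table, build_or_curve
from .misclassification import roc_points, sens_spec_curve
from .simulate import assemble_cohort, draw_base

__all__ = ["ResultBundle", "run_grid", "write_bundle", "render_figures",
           "ROC_TRUE_CUTOFFS"]

logger = logging.getLogger(__name__)

#: True-exposure cutoffs (in SD units) for which ROC curves are built.
ROC_TRUE_CUTOFFS = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class ResultBundle:
    """All analysis products of one study run, as long-format tables."""

    or_curves: pd.DataFrame
    category_or: pd.DataFrame
    sens_spec: pd.DataFrame
    roc: pd.DataFrame
    manifest: dict


def _versions() -> dict:
    import matplotlib
    import scipy
    import statsmodels

    from . import __version__

    return {
        "orcurve": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }


def run_grid(study: StudyGrid) -> ResultBundle:
    """Run every scenario of the grid and collect the four products.

    One base cohort (covariates, inclusion, error quantiles) is drawn
    per master seed and reused for every scenario. A failing scenario is
    recorded in the manifest and skipped; the sweep continues.
    """
    t0 = time.perf_counter()
    grid = make_dichotomy_grid(study.grid_lo, study.grid_hi, study.grid_step)
    base = draw_base(study.base.replace(n=study.n, seed=study.master_seed))
    or_parts, cat_parts, ss_parts, roc_parts = [], [], [], []
    failures: list[dict] = []
    for shape, beta1, sigma2, config in study.scenarios():
        sid = scenario_id(shape, beta1, sigma2)
        try:
            cohort = assemble_cohort(base, config)
            ids = {"scenario": sid, "shape": shape, "beta1": beta1, "sigma2": sigma2}

            curve = build_or_curve(cohort, grid, "w1", scenario=sid)
            or_parts.append(curve.table.assign(**ids, exposure_source="w1"))
            if sigma2 == study.sigma2_values[0]:
                # error-free reference curve, once per (shape, effect size)
                ref = build_or_curve(cohort, grid, "x1", scenario=sid)
                or_parts.append(ref.table.assign(**ids, exposure_source="x1"))

            cat = build_category_table(cohort, study.delta_values, "w1", scenario=sid)
            cat_parts.append(cat.table.assign(**ids))

            ss_parts.append(sens_spec_curve(cohort, grid).assign(**ids))

            x1 = cohort.frame["x1"].to_numpy()
            sweep = grid.resolve(
                float(cohort.frame["w1"].mean()), float(cohort.frame["w1"].std())
            )
            for k in ROC_TRUE_CUTOFFS:
                phi_true = float(x1.mean() + k * x1.std())
                roc = roc_points(cohort, phi_true, sweep)
                roc_parts.append(
                    roc.points.assign(
                        **ids, phi_true_sd=k, phi_true=phi_true, auc=roc.auc
                    )
                )
        except Exception as exc:  # record and continue
            logger.warning("scenario %s failed: %s", sid, exc)
            failures.append({"scenario": sid, "error": str(exc)})
    manifest = {
        "study": {
            "shapes": list(study.shapes),
            "beta1_values": list(study.beta1_values),
            "sigma2_values": list(study.sigma2_values),
            "grid": [study.grid_lo, study.grid_hi, study.grid_step],
            "delta_values": list(study.delta_values),
            "n": study.n,
            "master_seed": study.master_seed,
            "base_config": study.base.to_dict(),
        },
        "versions": _versions(),
        "failures": failures,
        "runtime_s": round(time.perf_counter() - t0, 3),
    }
    empty = pd.DataFrame()
    return ResultBundle(
        or_curves=pd.concat(or_parts, ignore_index=True) if or_parts else empty,
        category_or=pd.concat(cat_parts, ignore_index=True) if cat_parts else empty,
        sens_spec=pd.concat(ss_parts, ignore_index=True) if ss_parts else empty,
        roc=pd.concat(roc_parts, ignore_index=True) if roc_parts else empty,
        manifest=manifest,
    )


def write_bundle(bundle: ResultBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the four product CSVs and the manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("or_curves", bundle.or_curves),
        ("category_or", bundle.category_or),
        ("sens_spec", bundle.sens_spec),
        ("roc", bundle.roc),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    p = outdir / "manifest.json"
    p.write_text(json.dumps(bundle.manifest, indent=2))
    paths["manifest"] = p
    return paths


# ---------------------------------------------------------------------------
# figures


def _facet_axes(n_rows, n_cols, **kw):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        n_rows, n_cols, figsize=(3.2 * n_cols, 2.6 * n_rows),
        squeeze=False, sharex=True, **kw,
    )
    return fig, axes


def _save(fig, outdir: Path, stem: str) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        p = outdir / f"{stem}.{ext}"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        paths.append(p)
    import matplotlib.pyplot as plt

    plt.close(fig)
    return paths


def render_figures(bundle: ResultBundle, outdir: str | Path) -> list[Path]:
    """Render the study's figure types from the bundle tables.

    One OR-curve panel grid (shape x effect size, a line per error level
    plus the error-free reference), one category-OR grid, one
    sensitivity/specificity grid and one ROC grid. Missing (flagged)
    points appear as gaps. An empty bundle produces no files.
    """
    if bundle.or_curves.empty:
        logger.warning("empty result bundle; no figures rendered")
        return []
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    oc = bundle.or_curves
    shapes = sorted(oc["shape"].unique())
    betas = sorted(oc["beta1"].unique())
    sigmas = sorted(oc["sigma2"].unique())

    fig, axes = _facet_axes(len(shapes), len(betas))
    for i, shape in enumerate(shapes):
        for j, beta1 in enumerate(betas):
            ax = axes[i][j]
            sub = oc[(oc["shape"] == shape) & (oc["beta1"] == beta1)]
            ref = sub[sub["exposure_source"] == "x1"]
            if len(ref):
                ax.plot(ref["phi"], ref["or1"], "k--", lw=1, label="error-free (X1)")
            for s2 in sigmas:
                line = sub[(sub["exposure_source"] == "w1") & (sub["sigma2"] == s2)]
                ax.plot(line["phi"], line["or1"], lw=1, label=f"$\\sigma^2$={s2:g}")
            ax.set_title(f"{shape}, $\\beta_1$={beta1:g}", fontsize=9)
            ax.set_yscale("log")
            if i == len(shapes) - 1:
                ax.set_xlabel("cutoff $\\varphi$ (SD units)")
            if j == 0:
                ax.set_ylabel("OR")
    axes[0][-1].legend(fontsize=6)
    paths += _save(fig, outdir, "or_curves")

    cat = bundle.category_or
    if len(cat):
        fig, axes = _facet_axes(len(shapes), len(betas))
        for i, shape in enumerate(shapes):
            for j, beta1 in enumerate(betas):
                ax = axes[i][j]
                sub = cat[(cat["shape"] == shape) & (cat["beta1"] == beta1)]
                for s2 in sigmas:
                    for k, marker in zip((1, 2, 4, 5), "ovs^"):
                        pts = sub[(sub["sigma2"] == s2) & (sub["category"] == k)]
                        ax.plot(
                            pts["delta"], pts["or"], marker=marker, ms=2.5, lw=0.7,
                            alpha=0.4 + 0.6 * (s2 == min(sigmas)),
                            label=f"cat {k}" if s2 == sigmas[0] else None,
                        )
                ax.set_title(f"{shape}, $\\beta_1$={beta1:g}", fontsize=9)
                ax.set_yscale("log")
                if i == len(shapes) - 1:
                    ax.set_xlabel("reference width $\\delta$ (SD)")
                if j == 0:
                    ax.set_ylabel("OR vs category 3")
        axes[0][-1].legend(fontsize=6)
        paths += _save(fig, outdir, "category_or")

    ss = bundle.sens_spec
    if len(ss):
        fig, axes = _facet_axes(len(shapes), len(betas))
        for i, shape in enumerate(shapes):
            for j, beta1 in enumerate(betas):
                ax = axes[i][j]
                sub = ss[
                    (ss["shape"] == shape) & (ss["beta1"] == beta1)
                    & (ss["sigma2"] == max(sigmas))
                ]
                for group, color in zip(("cases", "controls"), ("C3", "C0")):
                    g = sub[sub["group"] == group]
                    ax.plot(g["phi"], g["sensitivity"], color=color, lw=1,
                            label=f"sens, {group}")
                    ax.plot(g["phi"], g["specificity"], color=color, lw=1, ls="--",
                            label=f"spec, {group}")
                ax.set_title(f"{shape}, $\\beta_1$={beta1:g}", fontsize=9)
                if i == len(shapes) - 1:
                    ax.set_xlabel("cutoff $\\varphi$ (SD units)")
                if j == 0:
                    ax.set_ylabel("sens / spec")
        axes[0][-1].legend(fontsize=6)
        paths += _save(fig, outdir, "sens_spec")

    roc = bundle.roc
    if len(roc):
        fig, axes = _facet_axes(len(shapes), len(betas))
        for i, shape in enumerate(shapes):
            for j, beta1 in enumerate(betas):
                ax = axes[i][j]
                sub = roc[
                    (roc["shape"] == shape) & (roc["beta1"] == beta1)
                    & (roc["sigma2"] == max(sigmas))
                ]
                for k in sorted(sub["phi_true_sd"].unique()):
                    pts = sub[sub["phi_true_sd"] == k]
                    ax.plot(pts["fpr"], pts["tpr"], lw=0.8, label=f"$\\varphi$={k:g}")
                ax.plot([0, 1], [0, 1], "k:", lw=0.5)
                ax.set_title(f"{shape}, $\\beta_1$={beta1:g}", fontsize=9)
                if i == len(shapes) - 1:
                    ax.set_xlabel("1 - specificity")
                if j == 0:
                    ax.set_ylabel("sensitivity")
        axes[0][-1].legend(fontsize=5)
        paths += _save(fig, outdir, "roc")
    return paths
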