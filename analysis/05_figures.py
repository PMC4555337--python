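#!/usr/bin/env python
"""Render the study's figures from the persisted result tables.

Reads the tables under ``results/study/`` and writes the four figure
types (OR curves by error level, category ORs by reference width,
sensitivity/specificity by stratum, ROC panels) as PNG + SVG next to
them.
"""

import json
from pathlib import Path

import pandas as pd

from orcurve import render_figures
from orcurve.runner import ResultBundle

STUDY = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    bundle = ResultBundle(
        or_curves=pd.read_csv(STUDY / "or_curves.csv"),
        category_or=pd.read_csv(STUDY / "category_or.csv"),
        sens_spec=pd.read_csv(STUDY / "sens_spec.csv"),
        roc=pd.read_csv(STUDY / "roc.csv"),
        manifest=json.loads((STUDY / "manifest.json").read_text()),
    )
    for p in render_figures(bundle, STUDY):
        print(f"wrote {p}")


if __name__ == "__main__":
    main()
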