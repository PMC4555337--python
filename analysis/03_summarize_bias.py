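#!/usr/bin/env python
"""Summarize how measurement error and cutoff placement distort the OR.

Reads ``results/study/or_curves.csv`` (produced by 02_run_study.py) and
tabulates, for each shape and effect size, the OR at cutoffs -2, -1, 0,
+1, +2 SD for every error variance. Prints the two headline patterns —
attenuation toward the null at the central cutoff as error grows, and
overestimation at the threshold model's inflection point — and writes
``results/tables/bias_summary.csv``.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    oc = pd.read_csv(ROOT / "study" / "or_curves.csv")
    w1 = oc[oc["exposure_source"] == "w1"]
    sel = w1[w1["phi"].round(1).isin([-2.0, -1.0, 0.0, 1.0, 2.0])]
    summary = sel.pivot_table(
        index=["shape", "beta1", "phi"], columns="sigma2", values="or1"
    ).round(3)
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "bias_summary.csv")
    print("OR by cutoff (rows) and error variance (columns):\n")
    print(summary.to_string())

    central = summary.xs(0.0, level="phi")
    attenuated = (central.diff(axis=1).iloc[:, 1:] < 0).all(axis=1)
    print(f"\ncentral-cutoff OR strictly decreasing in sigma2: "
          f"{int(attenuated.sum())}/{len(attenuated)} (shape, beta1) cells")

    thr = summary.xs("threshold", level="shape").xs(-1.0, level="phi")
    over = thr[1.0] > thr[0.0]
    print("threshold model at the inflection (-1 SD): OR with sigma2=1 "
          f"exceeds the no-error OR in {int(over.sum())}/{len(over)} effect sizes")
    print(f"\nwrote {out / 'bias_summary.csv'}")


if __name__ == "__main__":
    main()
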