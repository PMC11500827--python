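#!/usr/bin/env python
"""Cohort statistics: which features track impairment, and which pair
predicts it best.

Reads results/features.csv (from 03) and computes, per feature, the
regression against UEFM, the one-way ANOVA across the severe (<30),
moderate (30-49) and mild (>=50) groups, and pooled-SD Cohen's D with
t-tests for four group contrasts.  Then runs the prefiltered minimum-AIC
backward elimination of a multivariate UEFM model and reports the
selected variables with their variance inflation factors.

Writes results/feature_stats.csv and results/elimination_trace.json.
"""

import json
from pathlib import Path

import pandas as pd

from qome.pipeline import cohort_statistics

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    feats = pd.read_csv(ROOT / "results" / "features.csv", index_col=0)
    uefm = feats.pop("uefm").to_numpy()
    result = cohort_statistics(feats, uefm)

    out = ROOT / "results"
    result.table.to_csv(out / "feature_stats.csv")
    trace = {
        "steps": result.trace.to_frame().to_dict(orient="records"),
        "prefiltered_out": result.trace.prefiltered_out,
        "selected_variables": result.trace.selected_variables,
        "selected_vif": (result.selected_vif.to_dict()
                         if result.selected_vif is not None else None),
    }
    (out / "elimination_trace.json").write_text(
        json.dumps(trace, indent=2, default=float))

    t = result.table
    print("strongest severe-vs-moderate separator:",
          t["abs_d_1v2"].idxmax(),
          f"(|D|={t['abs_d_1v2'].max():.2f})")
    print("strongest moderate-vs-mild separator:",
          t["abs_d_2v3"].idxmax(),
          f"(|D|={t['abs_d_2v3'].max():.2f})")
    print("prefiltered out (not significant vs UEFM):",
          list(result.trace.prefiltered_out))
    print("minimum-AIC model:", result.trace.selected_variables)
    if result.selected_vif is not None:
        print("VIF of selected variables:",
              {k: round(v, 2) for k, v in result.selected_vif.items()})


if __name__ == "__main__":
    main()
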