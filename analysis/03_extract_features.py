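#!/usr/bin/env python
"""Per-subject movement-experience features and group tilt distributions.

Regenerates the study cohort and computes, per subject, the ten
quality-of-movement-experience features (tilt kurtosis/skewness/variance,
acceleration and angular-velocity magnitude ratios and means, Sample
Entropy of acceleration, angular velocity and tilt) plus the inactive
fraction.  Also averages the per-subject 91-bin tilt histograms within
each impairment group, the view in which postural stagnation of the
severe group is visible as a sharp peak near 95 degrees.

Writes results/features.csv and results/tilt_distribution_by_group.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from qome.cohort import assign_groups
from qome.features import TILT_EDGES
from qome.pipeline import cohort_features
from qome.synthetic import generate_cohort

SEED = 7
N_SUBJECTS = 22
DURATION_S = 1200.0

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = generate_cohort(N_SUBJECTS, seed=SEED, duration_s=DURATION_S)
    uefm = np.array([p.uefm for p, _ in cohort], float)
    feats, records = cohort_features([rec for _, rec in cohort])
    feats.insert(0, "uefm", uefm)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    feats.to_csv(out / "features.csv")

    groups = assign_groups(uefm)
    centers = 0.5 * (TILT_EDGES[:-1] + TILT_EDGES[1:])
    dist = pd.DataFrame({"tilt_deg": centers})
    for g in (1, 2, 3):
        hists = [r.tilt_hist.normalized for r, gg in zip(records, groups)
                 if gg == g]
        dist[f"group{g}"] = np.mean(hists, axis=0)
    dist.to_csv(out / "tilt_distribution_by_group.csv", index=False)

    print(f"features for {N_SUBJECTS} subjects -> results/features.csv")
    for g in (1, 2, 3):
        peak = dist[f"group{g}"].max()
        at = dist.loc[dist[f"group{g}"].idxmax(), "tilt_deg"]
        print(f"group {g}: tilt-distribution peak {peak:.3f} at {at:.0f} deg "
              f"({(groups == g).sum()} subjects)")


if __name__ == "__main__":
    main()
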