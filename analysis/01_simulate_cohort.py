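#!/usr/bin/env python
"""Simulate the study cohort.

Generates a 22-subject synthetic wrist-IMU cohort (20 simulated minutes
per subject at 52.6 Hz) with known impairment gradients, writes the
subject metadata and latent ground truth under results/cohort/, and the
(large) per-subject recording CSVs under scratch/cohort/.

Downstream scripts regenerate the recordings from the same seed instead
of re-reading the CSVs, so this script is optional for the rest of the
analysis; it exists to materialize the data a collaborator would inspect.
"""

from pathlib import Path

import numpy as np

from qome.synthetic import generate_cohort, write_cohort

SEED = 7
N_SUBJECTS = 22
DURATION_S = 1200.0

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = generate_cohort(N_SUBJECTS, seed=SEED, duration_s=DURATION_S)
    write_cohort(cohort, ROOT / "scratch" / "cohort", seed=SEED)

    # small, text-only summary of the cohort under results/
    out = ROOT / "results" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    import pandas as pd
    rows = [{"subject_id": p.subject_id, "uefm": p.uefm,
             "active_fraction": round(p.active_fraction, 4),
             "tilt_concentration": round(p.tilt_concentration, 4),
             "complexity_level": round(p.complexity_level, 4),
             "speed_scale": round(p.speed_scale, 4)}
            for p, _ in cohort]
    pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False)

    uefm = np.array([p.uefm for p, _ in cohort])
    print(f"simulated {N_SUBJECTS} subjects, UEFM {uefm.min()}-{uefm.max()}")
    print(f"recordings in scratch/cohort/, profiles in {out}/profiles.csv")


if __name__ == "__main__":
    main()
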