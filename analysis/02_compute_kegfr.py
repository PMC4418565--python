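"""Compute per-timepoint predictors for the simulated cohort.

For every subject and analysis timepoint (4/8/12 h): the raw markers,
their single-sample steady-state eGFR (CKD-EPI), and the kinetic GFR
from each consecutive concentration pair (anchor 4 h, CKD-EPI
back-calculated production, Vd = 0.6/0.2 L/kg, negatives clamped).
There is no kinetic cystatin estimate at 4 h because no 0 h cystatin
sample exists.

Reads results/cohort/; writes results/prediction_dataset.csv.
"""

from pathlib import Path

import numpy as np

from kegfr.pipeline import build_prediction_dataset
from kegfr.synthetic import read_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    dataset = build_prediction_dataset(cohort)
    dataset.to_csv(ROOT / "prediction_dataset.csv", index=False)
    print(f"wrote {ROOT / 'prediction_dataset.csv'} ({len(dataset)} rows)")
    for col in ("KeGFR_sCr", "KeGFR_pCysC"):
        pre = dataset.get(f"{col}_preclamp")
        if pre is not None:
            n_neg = int((pre < 0).sum())
            n_tot = int(np.isfinite(pre).sum())
            print(f"  {col}: {n_tot} estimates, {n_neg} negative (clamped to 0)")


if __name__ == "__main__":
    main()
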