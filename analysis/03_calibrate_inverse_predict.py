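#!/usr/bin/env python
"""Log-log calibration of neonatal TSH on maternal serum TCDD and inverse
prediction of the serum concentration at the two TSH thresholds.

Fits the calibration line on a sampled synthetic cohort (n = 51) and, for
reference, evaluates the fixed design relation the generator embeds (5
uU/mL at 235 ppt, 10 uU/mL at 1513.56 ppt).  Inverse predictions carry 95%
confidence sets under both the approximate-SE and Fieller constructions;
upper bounds above 1e7 ppt are reported as "> 1e7".

Writes results/calibration_fit.csv and results/inverse_predictions.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from rfduq.calibration import fit_loglog, inverse_predict
from rfduq.synthetic_data import default_tsh_params, generate_tsh_cohort, population_fit

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    params = default_tsh_params(seed=args.seed)
    pairs, _ = generate_tsh_cohort(params)
    fits = {"sampled_cohort": fit_loglog(pairs), "fixed_design": population_fit(params)}

    pd.DataFrame(
        [
            {"fit": name, "slope": f.slope, "intercept": f.intercept,
             "residual_se": f.residual_se, "n": f.n}
            for name, f in fits.items()
        ]
    ).to_csv(OUT / "calibration_fit.csv", index=False)

    rows = []
    for name, fit in fits.items():
        for threshold in (5.0, 10.0):
            for method in ("approx_se", "fieller"):
                p = inverse_predict(fit, threshold, method=method)
                rows.append(
                    {
                        "fit": name,
                        "threshold_tsh_uU_mL": threshold,
                        "method": method,
                        "point_ppt": p.point,
                        "ci_low_ppt": p.ci_low,
                        "ci_high_ppt": p.ci_high,
                        "ci_kind": p.kind.value,
                        "upper_display": p.display_upper(),
                    }
                )
    preds = pd.DataFrame(rows)
    preds.to_csv(OUT / "inverse_predictions.csv", index=False)
    print(preds.round(2).to_string(index=False))
    print()
    print(
        "The serum concentration at the clinical 10 uU/mL threshold is an "
        "order of magnitude above the 5 uU/mL screening value, with intervals "
        "spanning a factor of ten or more: the POD is weakly determined."
    )


if __name__ == "__main__":
    main()
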