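"""Anchored MAIC: reweight the reference IPD to the comparator trial's
aggregate baseline and combine anchored hazard ratios by the Bucher method.

The comparator trial's published anchored OS HR (0.590 after its own
two-stage correction) enters as config; its log-scale SE is an assumption
(no CI is published).  Outputs: per-patient weights, the balance table
(before / target / after), and the indirect HR with its CI.
"""
import json
from pathlib import Path

import pandas as pd

from psmcea.ipd import read_ipd
from psmcea.maic import (
    KEYNOTE_BASELINE, MATCHING_COVARIATES, anchored_maic, weighted_moments,
)

OUT = Path(__file__).resolve().parents[1] / "results"

HR_COMP_OS = 0.590     # comparator active vs shared chemo anchor, published
HR_COMP_LOG_SE = 0.15  # assumption: no CI printed for the adjusted HR


def main() -> None:
    ipd = read_ipd(OUT / "ipd.csv")
    res = anchored_maic(ipd, KEYNOTE_BASELINE, HR_COMP_OS, HR_COMP_LOG_SE)

    before = {c: float(ipd[c].mean()) for c in MATCHING_COVARIATES}
    after = weighted_moments(ipd, res.weights)
    balance = pd.DataFrame({
        "covariate": MATCHING_COVARIATES,
        "before": [before[c] for c in MATCHING_COVARIATES],
        "target": [KEYNOTE_BASELINE[c] for c in MATCHING_COVARIATES],
        "after": [after[c] for c in MATCHING_COVARIATES],
    })
    balance.to_csv(OUT / "maic_balance.csv", index=False)
    print(balance.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print(f"\neffective sample size: {res.ess:.1f} of {len(ipd)}")
    print(f"weighted anchored OS HR (reference): {res.hr_ref_weighted:.3f}")
    print(f"Bucher indirect OS HR (reference vs comparator): "
          f"{res.hr_ref_vs_comp:.3f} "
          f"(95% CI {res.hr_ref_vs_comp_ci[0]:.3f}-{res.hr_ref_vs_comp_ci[1]:.3f})")

    pd.DataFrame({"patient_id": ipd["patient_id"], "weight": res.weights}) \
        .to_csv(OUT / "maic_weights.csv", index=False)
    (OUT / "maic_hrs.json").write_text(json.dumps({
        "ess": res.ess,
        "hr_ref_weighted": res.hr_ref_weighted,
        "hr_ref_weighted_log_se": res.hr_ref_weighted_se,
        "hr_comp": res.hr_comp,
        "hr_comp_log_se": res.hr_comp_se,
        "hr_ref_vs_comp": res.hr_ref_vs_comp,
        "hr_ref_vs_comp_ci": list(res.hr_ref_vs_comp_ci),
    }, indent=1))
    print(f"wrote {OUT / 'maic_balance.csv'}, maic_weights.csv, maic_hrs.json")


if __name__ == "__main__":
    main()
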