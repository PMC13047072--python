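#!/usr/bin/env python
"""Risk-factor modelling: univariate screen then stepwise logistic selection.

Builds the complete-case design (cohort vs background; sex coded female=0 /
male=1, age and weight per unit, top comorbidity and screened-drug
indicators), screens each candidate alone, then selects a multivariate
model by forward/backward likelihood-ratio steps at alpha = 0.05.
"""

import argparse
import json
from pathlib import Path

from cheilitis_pv.report_store import read_reports
from cheilitis_pv.risk_model import (
    build_design,
    results_to_frame,
    stepwise_select,
    univariate_screen,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--background", type=Path, default=Path("results/background.csv"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--drugs", nargs="*", default=["DRUG_001", "DRUG_004", "DRUG_009"])
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_reports([args.cohort], dialect="simple_csv")
    background = read_reports([args.background], dialect="simple_csv")
    design = build_design(cohort, background, drugs=args.drugs)
    print(f"design: {len(design)} complete-case reports, "
          f"{int(design['outcome'].sum())} cases, "
          f"{design.shape[1] - 1} candidate terms")

    uni = univariate_screen(design)
    step = stepwise_select(design, alpha=args.alpha)
    args.out.mkdir(parents=True, exist_ok=True)
    results_to_frame(uni + step.results).to_csv(args.out / "risk_factors.csv",
                                                index=False)
    (args.out / "stepwise_trace.json").write_text(json.dumps(step.trace, indent=2))

    print(f"stepwise (alpha={args.alpha}) selected: {step.final_terms}")
    for r in step.results:
        if r.included:
            print(f"  {r.term}: OR={r.or_value:.3f} "
                  f"({r.ci[0]:.3f}-{r.ci[1]:.3f}) p={r.p_value:.2g}")


if __name__ == "__main__":
    main()
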