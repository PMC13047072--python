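#!/usr/bin/env python
"""Cohort description: demographic blocks and time-to-onset summary.

Produces the summary table (counts and percentages under the documented
denominator conventions) and the TTO median/IQR with binned counts.
"""

import argparse
from pathlib import Path

from cheilitis_pv.descriptives import summarize_cohort, tto_summary
from cheilitis_pv.report_store import read_reports


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_reports([args.cohort], dialect="simple_csv")
    table = summarize_cohort(cohort)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(args.out / "cohort_summary.csv", index=False)

    print(f"cohort: {len(cohort)} reports")
    for variable in ("Sex", "Age", "Weight", "Outcomes", "TTO"):
        rows = table.block(variable)
        if rows:
            top = max(rows, key=lambda r: r.count)
            print(f"  {variable}: largest category {top.category!r} "
                  f"{top.count} ({top.percent}%) of {top.denominator}")

    tto = tto_summary(cohort)
    if tto.median_days is not None:
        print(f"  TTO median {tto.median_days:.0f} days "
              f"(IQR {tto.iqr[0]:.0f}-{tto.iqr[1]:.0f}), "
              f"{tto.n_unknown} unknown")


if __name__ == "__main__":
    main()
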