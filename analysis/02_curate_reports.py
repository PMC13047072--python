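#!/usr/bin/env python
"""Curate the simulated corpus: deduplicate, apply exclusions, split cohort.

Reads results/corpus.csv, retains one report per case (latest version),
drops reports with no drug or no reaction record, and separates the
cheilitis cohort from the full background.
"""

import argparse
import json
from pathlib import Path

from cheilitis_pv.report_store import curate_pipeline, read_reports, write_simple_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("results/corpus.csv"))
    ap.add_argument("--dialect", choices=["simple_csv", "faers_ascii"],
                    default="simple_csv")
    ap.add_argument("--event", default="Cheilitis")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    reports = read_reports([args.input] if args.input.is_file() else args.input,
                           dialect=args.dialect)
    cohort, background, log = curate_pipeline(reports, args.event)
    args.out.mkdir(parents=True, exist_ok=True)
    write_simple_csv(cohort, args.out / "cohort.csv")
    write_simple_csv(background, args.out / "background.csv")
    (args.out / "curation_log.json").write_text(json.dumps(log.as_dict(), indent=2))
    print(f"{log.n_raw} raw -> {log.n_after_dedup} after dedup -> "
          f"{log.n_final} retained ({log.n_excluded_nondrug} without drugs, "
          f"{log.n_excluded_incomplete} incomplete)")
    print(f"cohort with {args.event!r}: {len(cohort)} reports")


if __name__ == "__main__":
    main()
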