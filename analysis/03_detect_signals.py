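#!/usr/bin/env python
"""Disproportionality signal detection over the curated background corpus.

Fits the gamma-Poisson prior on all (n, E) cells, computes ROR/PRR/chi2 and
EBGM/EB05/EB95 for every drug-event pair with at least three co-reports,
applies the default signal rules, and reports which cheilitis pairs fire.
"""

import argparse
from pathlib import Path

from cheilitis_pv.contingency import build_cell_set
from cheilitis_pv.disproportionality import fit_prior, signal_table, write_signals


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("results/background.csv"))
    ap.add_argument("--min-n", type=int, default=3)
    ap.add_argument("--event", default="Cheilitis")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    from cheilitis_pv.report_store import read_reports

    reports = read_reports([args.input], dialect="simple_csv")
    prior = fit_prior(build_cell_set(reports, min_n=1))
    records = signal_table(reports, min_n=args.min_n, prior=prior)
    args.out.mkdir(parents=True, exist_ok=True)
    write_signals(records, args.out / "signals.csv")
    prior.to_json(args.out / "prior.json")

    event_key = args.event.casefold()
    hits = [r for r in records if r.event == event_key and r.flags]
    print(f"{len(records)} pairs with n >= {args.min_n}; "
          f"{len(hits)} flagged for {args.event!r}:")
    for r in sorted(hits, key=lambda r: -r.ror):
        print(f"  {r.drug}: n={r.n} ROR={r.ror:.2f} "
              f"({r.ror_ci[0]:.2f}-{r.ror_ci[1]:.2f}) EBGM={r.ebgm:.2f} "
              f"[{';'.join(sorted(r.flags))}]")


if __name__ == "__main__":
    main()
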