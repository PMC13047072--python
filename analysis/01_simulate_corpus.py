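#!/usr/bin/env python
"""Simulate a FAERS-like corpus with planted cheilitis associations.

Writes the corpus in the simple_csv dialect plus the ground truth (planted
odds multipliers, realized pair counts) so later stages can be scored
against what was actually planted.
"""

import argparse
import json
from pathlib import Path

from cheilitis_pv.report_store import write_simple_csv
from cheilitis_pv.synthetic_data import PlantedPair, SyntheticConfig, generate

PLANTED = [
    PlantedPair(drug="DRUG_001", event="Cheilitis", theta=12.0),
    PlantedPair(drug="DRUG_004", event="Cheilitis", theta=5.0),
    PlantedPair(drug="DRUG_009", event="Cheilitis", theta=2.0),
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-reports", type=int, default=50000)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SyntheticConfig(
        n_reports=args.n_reports,
        planted=PLANTED,
        covariate_effects={"sex_male": -0.26, "age_years": -0.005, "weight_kg": -0.005},
        seed=args.seed,
    )
    reports, truth = generate(cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    write_simple_csv(reports, args.out / "corpus.csv")
    (args.out / "truth.json").write_text(
        json.dumps(
            {
                "planted": [p.model_dump() for p in truth.planted],
                "covariate_effects": truth.covariate_effects,
                "realized_pair_counts": {
                    f"{d}|{e}": c for (d, e), c in truth.realized_pair_counts.items()
                },
                "n_reports": truth.n_reports,
                "n_rejected_zero_event": truth.n_rejected,
                "seed": args.seed,
            },
            indent=2,
        )
    )
    print(f"wrote {len(reports)} reports to {args.out/'corpus.csv'}")
    for (d, e), c in truth.realized_pair_counts.items():
        print(f"  planted {d} -> {e}: {c} co-reports")


if __name__ == "__main__":
    main()
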