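"""Cohort description: demographic blocks and time-to-onset summaries.

Percentage conventions follow how published spontaneous-report cohort tables
are actually computed:

* within-block denominators: each variable block (year, sex, age group,
  weight group, reporter, TTO category) is divided by the sum of its own row
  counts — for blocks whose rows cover every case this equals the cohort
  size, while blocks with a handful of uncategorizable cases (e.g. partial
  dates) implicitly drop them from the denominator;
* outcomes are divided by the total number of outcome mentions (one report
  may carry several seriousness outcomes);
* countries are divided by the number of reports with a known country.

All percentages are rounded half-up to two decimals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .report_store import CaseReport, Outcome, Reporter, Sex
from .stratified import AGE_BINS, NumericBin, SENSITIVITY_WEIGHT_BINS

__all__ = [
    "SummaryRow",
    "SummaryTable",
    "TTOSummary",
    "percent",
    "block_percentages",
    "summarize_cohort",
    "compute_tto",
    "tto_summary",
    "TTO_BINS",
]

#: Time-to-onset bins in days: <2, 2-5, 5-7, 7-14, 14-28, >=28 (closed-left).
TTO_BINS = (
    NumericBin("<2", 0, 2),
    NumericBin("2-5", 2, 5),
    NumericBin("5-7", 5, 7),
    NumericBin("7-14", 7, 14),
    NumericBin("14-28", 14, 28),
    NumericBin(">=28", 28, float("inf")),
)


def percent(count: int, denominator: int) -> float:
    """100*count/denominator rounded half-up to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    exact = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(exact.quantize(Decimal("0.01"), ROUND_HALF_UP))


def block_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentages of each category against the block's own total."""
    total = sum(counts.values())
    return {k: percent(v, total) for k, v in counts.items()}


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    category: str
    count: int
    denominator: int
    percent: float
    denominator_kind: str  # all_cases | category_total | known_only | mention_total


@dataclass
class SummaryTable:
    rows: list[SummaryRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "category": r.category,
                    "count": r.count,
                    "denominator": r.denominator,
                    "percent": r.percent,
                    "denominator_kind": r.denominator_kind,
                }
                for r in self.rows
            ]
        )

    def block(self, variable: str) -> list[SummaryRow]:
        return [r for r in self.rows if r.variable == variable]


def _add_block(
    table: SummaryTable,
    variable: str,
    counts: "Counter[str]",
    order: Sequence[str],
    kind: str,
    denominator: int | None = None,
) -> None:
    denom = denominator if denominator is not None else sum(counts.values())
    if denom == 0:
        return
    for cat in order:
        if counts.get(cat, 0) == 0 and cat not in ("Unknown",):
            continue
        table.rows.append(
            SummaryRow(variable, cat, counts.get(cat, 0), denom,
                       percent(counts.get(cat, 0), denom), kind)
        )


_OUTCOME_LABELS = {
    Outcome.OTHER_SERIOUS: "Other serious",
    Outcome.HOSPITALIZATION: "Hospitalization",
    Outcome.DEATH: "Death",
    Outcome.LIFE_THREATENING: "Life threatening",
    Outcome.DISABILITY: "Disability",
    Outcome.REQUIRED_INTERVENTION: "Required intervention",
    Outcome.CONGENITAL_ANOMALY: "Congenital anomaly",
}

_REPORTER_LABELS = {
    Reporter.CONSUMER: "Consumer",
    Reporter.PHYSICIAN: "Physician",
    Reporter.OTHER_HEALTH_PROFESSIONAL: "Other health-professional",
    Reporter.PHARMACIST: "Pharmacist",
    Reporter.LAWYER: "Lawyer",
    Reporter.REGISTERED_NURSE: "Registered nurse",
    Reporter.UNKNOWN: "Unknown",
}


def summarize_cohort(
    cohort: Sequence[CaseReport],
    top_countries: int = 5,
) -> SummaryTable:
    """Table-1-style description of a (deduplicated) cohort."""
    table = SummaryTable()
    if not cohort:
        return table
    n = len(cohort)

    years = Counter(str(r.report_year) for r in cohort if r.report_year is not None)
    _add_block(table, "Year", years, sorted(years), "category_total")

    sexes = Counter()
    for r in cohort:
        sexes[{Sex.FEMALE: "Female", Sex.MALE: "Male", Sex.UNKNOWN: "Unknown"}[r.sex]] += 1
    _add_block(table, "Sex", sexes, ["Female", "Male", "Unknown"], "all_cases", n)

    ages = Counter()
    for r in cohort:
        if r.age_years is None:
            ages["Unknown"] += 1
        else:
            for b in AGE_BINS:
                if b.contains(r.age_years):
                    ages[b.label] += 1
                    break
    _add_block(table, "Age", ages, [*(b.label for b in AGE_BINS), "Unknown"],
               "category_total")

    weights = Counter()
    for r in cohort:
        if r.weight_kg is None:
            weights["Unknown"] += 1
        else:
            for b in SENSITIVITY_WEIGHT_BINS:
                if b.contains(r.weight_kg):
                    weights[b.label] += 1
                    break
    _add_block(table, "Weight", weights,
               [*(b.label for b in SENSITIVITY_WEIGHT_BINS), "Unknown"],
               "category_total")

    reporters = Counter(_REPORTER_LABELS[r.reporter] for r in cohort)
    _add_block(table, "Reporter", reporters, list(_REPORTER_LABELS.values()),
               "all_cases", n)

    countries = Counter(r.country for r in cohort if r.country)
    known = sum(countries.values())
    if known:
        top = [c for c, _ in countries.most_common(top_countries)]
        grouped = Counter({c: countries[c] for c in top})
        other = known - sum(grouped.values())
        if other:
            grouped["Other"] = other
        _add_block(table, "Country", grouped, [*top, "Other"], "known_only", known)

    mentions = Counter()
    for r in cohort:
        for o in r.outcomes:
            mentions[_OUTCOME_LABELS[o]] += 1
    _add_block(table, "Outcomes", mentions, list(_OUTCOME_LABELS.values()),
               "mention_total")

    tto = tto_summary(cohort)
    tto_counts = Counter({b.label: tto.category_counts[b.label] for b in TTO_BINS})
    tto_counts["Unknown"] = tto.n_unknown
    _add_block(table, "TTO", tto_counts, [*(b.label for b in TTO_BINS), "Unknown"],
               "category_total")
    return table


def compute_tto(report: CaseReport) -> int | None:
    """Days from the earliest suspect-drug start to event onset; negative -> unknown."""
    start = report.earliest_suspect_start()
    if start is None or report.event_onset_date is None:
        return None
    days = (report.event_onset_date - start).days
    return days if days >= 0 else None


@dataclass
class TTOSummary:
    median_days: float | None
    iqr: tuple[float, float] | None
    category_counts: dict[str, int]
    n_unknown: int
    n_known: int


def tto_summary(cohort: Sequence[CaseReport]) -> TTOSummary:
    """Median/IQR and binned counts of time-to-onset over a cohort."""
    values = []
    n_unknown = 0
    counts = {b.label: 0 for b in TTO_BINS}
    for r in cohort:
        tto = compute_tto(r)
        if tto is None:
            n_unknown += 1
            continue
        values.append(tto)
        for b in TTO_BINS:
            if b.contains(tto):
                counts[b.label] += 1
                break
    if values:
        arr = np.asarray(values, dtype=float)
        med = float(np.median(arr))
        q1, q3 = (float(v) for v in np.percentile(arr, [25, 75]))
        return TTOSummary(med, (q1, q3), counts, n_unknown, len(values))
    return TTOSummary(None, None, counts, n_unknown, 0)
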