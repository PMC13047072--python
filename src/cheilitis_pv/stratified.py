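"""Subgroup disproportionality and complete-case sensitivity analysis.

Subgroup analyses re-run the full disproportionality pipeline inside each
demographic stratum (age, sex or weight bins) and keep only pairs with at
least ``min_cases`` reports in the stratum — small-count subgroup estimates
are too unstable to report. The complete-case sensitivity analysis repeats
the primary analysis on reports with no missing age, sex or weight, and the
concordance report quantifies how many primary signals survive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .disproportionality import SignalCriteria, SignalRecord, signal_table
from .report_store import CaseReport, Sex

__all__ = [
    "NumericBin",
    "StratumSpec",
    "AGE_BINS",
    "SENSITIVITY_WEIGHT_BINS",
    "ConcordanceReport",
    "subgroup_signals",
    "complete_case_filter",
    "concordance",
]


@dataclass(frozen=True)
class NumericBin:
    """A labeled interval, half-open [lo, hi) by default.

    ``closed_right`` includes the upper endpoint; ``closed_left=False``
    excludes the lower one (e.g. the ">100 kg" bin is (100, inf)).
    """

    label: str
    lo: float
    hi: float
    closed_right: bool = False
    closed_left: bool = True

    def contains(self, v: float) -> bool:
        above = v >= self.lo if self.closed_left else v > self.lo
        below = v <= self.hi if self.closed_right else v < self.hi
        return above and below

    def overlaps(self, other: "NumericBin") -> bool:
        def below(x: "NumericBin", y: "NumericBin") -> bool:
            # does x start strictly before y ends?
            if x.lo < y.hi:
                return True
            return x.lo == y.hi and x.closed_left and y.closed_right

        return below(self, other) and below(other, self)


#: Age bins: <19, 19-44, 45-59, >=60 years (half-open intervals).
AGE_BINS = (
    NumericBin("<19", 0.0, 19.0),
    NumericBin("19-44", 19.0, 45.0),
    NumericBin("45-59", 45.0, 60.0),
    NumericBin(">=60", 60.0, float("inf")),
)

#: Sensitivity weight bins: <50, 50-100 (both boundaries inclusive), >100 kg.
SENSITIVITY_WEIGHT_BINS = (
    NumericBin("<50", 0.0, 50.0),
    NumericBin("50-100", 50.0, 100.0, closed_right=True),
    NumericBin(">100", 100.0, float("inf"), closed_left=False),
)


@dataclass(frozen=True)
class StratumSpec:
    """How to partition reports for a subgroup analysis.

    ``variable`` is one of age/sex/weight; numeric variables use ``bins``,
    sex uses its categorical levels. Reports with the variable missing are
    assigned the label ``"unknown"``.
    """

    variable: str
    bins: tuple[NumericBin, ...] = ()
    min_cases: int = 3

    def __post_init__(self) -> None:
        if self.variable not in ("age", "sex", "weight"):
            raise ValueError(f"unknown stratification variable: {self.variable!r}")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.variable != "sex" and not self.bins:
            raise ValueError(f"{self.variable} stratification requires bins")
        for i, b1 in enumerate(self.bins):
            for b2 in self.bins[i + 1:]:
                if b1.overlaps(b2):
                    raise ValueError(f"overlapping bins: {b1.label!r} and {b2.label!r}")

    def assign(self, report: CaseReport) -> str:
        if self.variable == "sex":
            return report.sex.value if report.sex != Sex.UNKNOWN else "unknown"
        value = report.age_years if self.variable == "age" else report.weight_kg
        if value is None:
            return "unknown"
        for b in self.bins:
            if b.contains(value):
                return b.label
        return "unknown"

    @classmethod
    def age(cls, min_cases: int = 3) -> "StratumSpec":
        return cls("age", AGE_BINS, min_cases)

    @classmethod
    def sex(cls, min_cases: int = 3) -> "StratumSpec":
        return cls("sex", (), min_cases)

    @classmethod
    def weight(cls, min_cases: int = 3) -> "StratumSpec":
        return cls("weight", SENSITIVITY_WEIGHT_BINS, min_cases)


def subgroup_signals(
    reports: Sequence[CaseReport],
    spec: StratumSpec,
    criteria: SignalCriteria | None = None,
    include_unknown: bool = True,
    roles: str = "all",
) -> dict[str, list[SignalRecord]]:
    """Per-stratum signal tables, dropping pairs with stratum n < min_cases."""
    by_stratum: dict[str, list[CaseReport]] = {}
    for r in reports:
        label = spec.assign(r)
        if label == "unknown" and not include_unknown:
            continue
        by_stratum.setdefault(label, []).append(r)

    out: dict[str, list[SignalRecord]] = {}
    for label in sorted(by_stratum):
        members = by_stratum[label]
        if not members:
            warnings.warn(f"stratum {label!r} has no reports", stacklevel=2)
            out[label] = []
            continue
        crit = criteria or SignalCriteria(min_n=spec.min_cases)
        out[label] = signal_table(members, min_n=spec.min_cases, criteria=crit,
                                  roles=roles)
    return out


def complete_case_filter(reports: Sequence[CaseReport]) -> list[CaseReport]:
    """Reports with age, sex and weight all present (the complete cases)."""
    return [
        r
        for r in reports
        if r.age_years is not None and r.weight_kg is not None and r.sex != Sex.UNKNOWN
    ]


@dataclass
class ConcordanceReport:
    """Overlap of flagged pairs between the primary and sensitivity analyses.

    ``retention_fraction`` = retained / primary signals (0 when the primary
    analysis flagged nothing).
    """

    n_signals_primary: int
    n_signals_sensitivity: int
    n_retained: int
    retention_fraction: float
    detail: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_signals_primary": self.n_signals_primary,
                    "n_signals_sensitivity": self.n_signals_sensitivity,
                    "n_retained": self.n_retained,
                    "retention_fraction": self.retention_fraction,
                    "detail": self.detail,
                },
                indent=2,
            )
        )


def _flagged_pairs(
    records: Sequence[SignalRecord], signal_flag: str
) -> set[tuple[str, str]]:
    return {(r.drug, r.event) for r in records if signal_flag in r.flags}


def concordance(
    primary: Sequence[SignalRecord],
    sensitivity: Sequence[SignalRecord],
    signal_flag: str = "ror_signal",
    primary_criteria: SignalCriteria | None = None,
    sensitivity_criteria: SignalCriteria | None = None,
) -> ConcordanceReport:
    """Compare flagged pairs between two analyses run with the same criteria."""
    if (
        primary_criteria is not None
        and sensitivity_criteria is not None
        and primary_criteria != sensitivity_criteria
    ):
        raise ValueError("primary and sensitivity analyses used different criteria")
    p = _flagged_pairs(primary, signal_flag)
    s = _flagged_pairs(sensitivity, signal_flag)
    retained = p & s
    detail = [
        {
            "drug": drug,
            "event": event,
            "in_primary": (drug, event) in p,
            "in_sensitivity": (drug, event) in s,
            "retained": (drug, event) in retained,
        }
        for (drug, event) in sorted(p | s)
    ]
    return ConcordanceReport(
        n_signals_primary=len(p),
        n_signals_sensitivity=len(s),
        n_retained=len(retained),
        retention_fraction=(len(retained) / len(p)) if p else 0.0,
        detail=detail,
    )
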