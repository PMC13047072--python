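"""2x2 drug-event contingency tables and expected counts under independence.

The unit of counting is the report: a report contributes at most once to a
drug's margin, an event's margin, and a (drug, event) cell, however many times
the drug or term is repeated within it. For the empirical Bayes shrinker the
module produces the full set of (n, E) cells over all observed pairs, where
E = (reports with drug)(reports with event)/N is the count expected if drug
and event were reported independently; stratified expectations sum the
within-stratum E (Mantel-Haenszel style).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

import pandas as pd

from .report_store import CaseReport, DrugRole, normalize_drug_name, normalize_term

__all__ = [
    "ContingencyTable",
    "CellExpectation",
    "report_exposures",
    "build_table",
    "build_cell_set",
    "stratified_cells",
    "cells_to_frame",
    "write_cells",
]

_SUSPECT_ROLES = (DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT)


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one drug-event pair against the whole corpus.

    a: drug and event; b: drug, no event; c: event, no drug; d: neither.
    """

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    event: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def expected_a(self) -> float:
        if self.n_total == 0:
            raise ValueError("empty table has no expected count")
        return self.n_drug * self.n_event / self.n_total

    def transpose(self) -> "ContingencyTable":
        """Swap drug/event roles: (a, b, c, d) -> (a, c, b, d)."""
        return ContingencyTable(self.a, self.c, self.b, self.d,
                                drug=self.event, event=self.drug)


@dataclass(frozen=True)
class CellExpectation:
    drug: str
    event: str
    n: int
    E: float
    stratum: str = ""

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.E <= 0:
            raise ValueError("E must be positive")


def report_exposures(
    reports: Sequence[CaseReport], roles: str = "all"
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Per-report (drug set, event set) with normalized names.

    roles='suspect_only' restricts exposure to primary/secondary suspects.
    """
    if roles not in ("all", "suspect_only"):
        raise ValueError(f"unknown roles filter: {roles!r}")
    out = []
    for r in reports:
        if roles == "suspect_only":
            ds = frozenset(
                normalize_drug_name(d.name) for d in r.drugs if d.role in _SUSPECT_ROLES
            )
        else:
            ds = frozenset(normalize_drug_name(d.name) for d in r.drugs)
        es = frozenset(normalize_term(e) for e in r.events)
        out.append((ds, es))
    return out


def build_table(
    reports: Sequence[CaseReport], drug: str, event: str, roles: str = "all"
) -> ContingencyTable:
    """Count the 2x2 cells for one drug-event pair by report-level membership."""
    dkey = normalize_drug_name(drug)
    ekey = normalize_term(event)
    a = b = c = d = 0
    for ds, es in report_exposures(reports, roles):
        has_d = dkey in ds
        has_e = ekey in es
        if has_d and has_e:
            a += 1
        elif has_d:
            b += 1
        elif has_e:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d, drug=dkey, event=ekey)


def _margins_and_pairs(
    exposures: Iterable[tuple[frozenset[str], frozenset[str]]]
) -> tuple[Counter, Counter, Counter, int]:
    drug_margin: Counter = Counter()
    event_margin: Counter = Counter()
    pair_counts: Counter = Counter()
    n_reports = 0
    for ds, es in exposures:
        n_reports += 1
        drug_margin.update(ds)
        event_margin.update(es)
        for dname in ds:
            for ename in es:
                pair_counts[(dname, ename)] += 1
    return drug_margin, event_margin, pair_counts, n_reports


def build_cell_set(
    reports: Sequence[CaseReport], min_n: int = 1, roles: str = "all"
) -> list[CellExpectation]:
    """All (n, E) cells over observed drug-event pairs with n >= min_n."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    drug_margin, event_margin, pair_counts, n_reports = _margins_and_pairs(
        report_exposures(reports, roles)
    )
    if n_reports == 0:
        return []
    cells = []
    for (dname, ename), n in sorted(pair_counts.items()):
        if n < min_n:
            continue
        e_val = drug_margin[dname] * event_margin[ename] / n_reports
        cells.append(CellExpectation(drug=dname, event=ename, n=n, E=e_val))
    return cells


class StratumAssigner(Protocol):
    def assign(self, report: CaseReport) -> str: ...


def stratified_cells(
    reports: Sequence[CaseReport],
    strata: StratumAssigner | Callable[[CaseReport], str],
    min_n: int = 1,
    roles: str = "all",
    complete_case: bool = False,
) -> list[CellExpectation]:
    """Cells with E summed over strata: E = sum_s E_s, n = sum_s n_s.

    ``strata`` assigns each report a stratum label; reports labelled
    ``"unknown"`` form their own stratum unless ``complete_case`` drops them.
    """
    assign = strata.assign if hasattr(strata, "assign") else strata
    by_stratum: dict[str, list[CaseReport]] = {}
    for r in reports:
        label = assign(r)
        if complete_case and label == "unknown":
            continue
        by_stratum.setdefault(label, []).append(r)

    total_n: Counter = Counter()
    total_e: dict[tuple[str, str], float] = {}
    for members in by_stratum.values():
        drug_margin, event_margin, pair_counts, n_s = _margins_and_pairs(
            report_exposures(members, roles)
        )
        for pair, n in pair_counts.items():
            total_n[pair] += n
            total_e[pair] = total_e.get(pair, 0.0) + (
                drug_margin[pair[0]] * event_margin[pair[1]] / n_s
            )
    return [
        CellExpectation(drug=dname, event=ename, n=total_n[(dname, ename)],
                        E=total_e[(dname, ename)])
        for (dname, ename) in sorted(total_n)
        if total_n[(dname, ename)] >= min_n
    ]


def cells_to_frame(cells: Sequence[CellExpectation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"drug": c.drug, "event": c.event, "stratum": c.stratum, "n": c.n, "E": c.E}
            for c in cells
        ],
        columns=["drug", "event", "stratum", "n", "E"],
    )


def write_cells(cells: Sequence[CellExpectation], path: str | Path) -> None:
    cells_to_frame(cells).to_csv(path, index=False)
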