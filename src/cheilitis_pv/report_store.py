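"""Reading, normalizing, deduplicating and curating spontaneous adverse-event reports.

Two input dialects are supported:

* ``faers_ascii`` — the quarterly ``$``-delimited ASCII tables (DEMO, DRUG,
  REAC, OUTC, THER) sharing a ``primaryid`` column, as released by the FDA
  Adverse Event Reporting System.
* ``simple_csv`` — a flat one-row-per-(report, drug, event) CSV used by the
  synthetic generator and for small fixtures; see :data:`SIMPLE_CSV_COLUMNS`.

Curation follows standard spontaneous-report practice: keep the latest
version of each case, drop reports with no drug or no reaction record, and
split the corpus into the event cohort and the full background.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DrugRole",
    "Sex",
    "Reporter",
    "Outcome",
    "DrugEntry",
    "CaseReport",
    "CurationLog",
    "CurationRules",
    "FormatError",
    "normalize_drug_name",
    "normalize_term",
    "parse_flexible_date",
    "read_reports",
    "write_simple_csv",
    "deduplicate",
    "curate",
    "curate_pipeline",
]


class FormatError(ValueError):
    """A required column or structure is missing from an input file."""


class DrugRole(str, enum.Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Reporter(str, enum.Enum):
    CONSUMER = "consumer"
    PHYSICIAN = "physician"
    PHARMACIST = "pharmacist"
    OTHER_HEALTH_PROFESSIONAL = "other_health_professional"
    REGISTERED_NURSE = "registered_nurse"
    LAWYER = "lawyer"
    UNKNOWN = "unknown"


class Outcome(str, enum.Enum):
    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    CONGENITAL_ANOMALY = "congenital_anomaly"
    REQUIRED_INTERVENTION = "required_intervention"
    OTHER_SERIOUS = "other_serious"


# FAERS OUTC_COD values.
_OUTC_CODES = {
    "DE": Outcome.DEATH,
    "LT": Outcome.LIFE_THREATENING,
    "HO": Outcome.HOSPITALIZATION,
    "DS": Outcome.DISABILITY,
    "CA": Outcome.CONGENITAL_ANOMALY,
    "RI": Outcome.REQUIRED_INTERVENTION,
    "OT": Outcome.OTHER_SERIOUS,
}
_OUTC_TO_CODE = {v: k for k, v in _OUTC_CODES.items()}

_OCCP_CODES = {
    "CN": Reporter.CONSUMER,
    "MD": Reporter.PHYSICIAN,
    "PH": Reporter.PHARMACIST,
    "OT": Reporter.OTHER_HEALTH_PROFESSIONAL,
    "RN": Reporter.REGISTERED_NURSE,
    "LW": Reporter.LAWYER,
}

_DRUG_ROLE_CODES = {
    "PS": DrugRole.PRIMARY_SUSPECT,
    "SS": DrugRole.SECONDARY_SUSPECT,
    "C": DrugRole.CONCOMITANT,
    "I": DrugRole.INTERACTING,
}

#: Salt/ester suffixes stripped from the end of drug names during
#: normalization. Configurable; no external dictionary is used.
DEFAULT_SALT_SUFFIXES = (
    "HYDROCHLORIDE",
    "HCL",
    "SODIUM",
    "POTASSIUM",
    "CALCIUM",
    "SULFATE",
    "SULPHATE",
    "MESYLATE",
    "MALEATE",
    "TARTRATE",
    "CITRATE",
    "ACETATE",
    "PHOSPHATE",
    "BESYLATE",
    "FUMARATE",
    "SUCCINATE",
)

_WS = re.compile(r"\s+")


def normalize_drug_name(
    name: str, salt_suffixes: Sequence[str] = DEFAULT_SALT_SUFFIXES
) -> str:
    """Uppercase, trim, collapse internal whitespace, strip trailing salt words."""
    out = _WS.sub(" ", name.strip().upper())
    changed = True
    while changed:
        changed = False
        for suffix in salt_suffixes:
            if out.endswith(" " + suffix):
                out = out[: -len(suffix) - 1].rstrip()
                changed = True
    return out


def normalize_term(term: str) -> str:
    """Normalize an event preferred term for case-insensitive exact matching."""
    return _WS.sub(" ", term.strip()).casefold()


def parse_flexible_date(raw: object) -> date | None:
    """Parse YYYYMMDD / YYYYMM / YYYY / ISO dates; anything else is missing.

    Partial dates use conventional midpoints: missing day -> 15, missing
    month/day -> July 1.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.upper() in {"NA", "NAN", "UNK", "UNKNOWN", "NONE"}:
        return None
    if s.endswith(".0"):  # numeric column read as float
        s = s[:-2]
    if re.fullmatch(r"\d{4}-\d{2}-\d{2}", s):
        try:
            return date.fromisoformat(s)
        except ValueError:
            return None
    if not re.fullmatch(r"\d{4}(\d{2})?(\d{2})?", s):
        return None
    try:
        if len(s) == 8:
            return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if len(s) == 6:
            return date(int(s[:4]), int(s[4:6]), 15)
        return date(int(s), 7, 1)
    except ValueError:
        return None


def _parse_float(raw: object, lo: float, hi: float, *, closed_lo: bool = True) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.upper() in {"NA", "NAN", "UNK", "UNKNOWN"}:
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    if (v < lo) or (not closed_lo and v == lo) or v > hi:
        return None
    return v


@dataclass(frozen=True)
class DrugEntry:
    """One drug record on a report."""

    name: str
    role: DrugRole = DrugRole.PRIMARY_SUSPECT
    start_date: date | None = None
    indication: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("drug name must be non-empty")


@dataclass
class CaseReport:
    """One spontaneous report after normalization.

    ``events`` holds MedDRA-style preferred terms; ``outcomes`` the seriousness
    categories. Demographics may be missing (``None`` / ``Sex.UNKNOWN``) —
    spontaneous reporting systems have high missingness and missing values are
    never imputed here.
    """

    case_id: str
    receipt_date: date | None = None
    report_version: int = 0
    report_year: int | None = None
    sex: Sex = Sex.UNKNOWN
    age_years: float | None = None
    weight_kg: float | None = None
    reporter: Reporter = Reporter.UNKNOWN
    country: str | None = None
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    outcomes: frozenset[Outcome] = frozenset()
    event_onset_date: date | None = None

    def __post_init__(self) -> None:
        if self.report_year is None and self.receipt_date is not None:
            self.report_year = self.receipt_date.year

    def drug_names(self) -> set[str]:
        return {d.name for d in self.drugs}

    def event_terms(self) -> set[str]:
        return {normalize_term(e) for e in self.events}

    def has_event(self, term: str, synonyms: Iterable[str] = ()) -> bool:
        wanted = {normalize_term(term), *(normalize_term(s) for s in synonyms)}
        return bool(self.event_terms() & wanted)

    def earliest_suspect_start(self) -> date | None:
        starts = [
            d.start_date
            for d in self.drugs
            if d.start_date is not None
            and d.role in (DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT)
        ]
        return min(starts) if starts else None


@dataclass
class CurationLog:
    n_raw: int = 0
    n_after_dedup: int = 0
    n_excluded_nondrug: int = 0
    n_excluded_incomplete: int = 0
    n_final: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_raw": self.n_raw,
            "n_after_dedup": self.n_after_dedup,
            "n_excluded_nondrug": self.n_excluded_nondrug,
            "n_excluded_incomplete": self.n_excluded_incomplete,
            "n_final": self.n_final,
        }


@dataclass(frozen=True)
class CurationRules:
    """Operationalization of 'incomplete or ambiguous documentation'.

    A report is excluded when it has no drug record (counted as non-drug) or
    no reaction record / out-of-window year (counted as incomplete).
    Demographic missingness never excludes a report at this stage; that is the
    job of the complete-case sensitivity filter.
    """

    year_min: int = 2004
    year_max: int = 2025
    require_drug: bool = True
    require_event: bool = True
    synonyms: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# simple_csv dialect
# ---------------------------------------------------------------------------

SIMPLE_CSV_COLUMNS = [
    "case_id",
    "receipt_date",
    "report_version",
    "sex",
    "age_years",
    "weight_kg",
    "reporter",
    "country",
    "drug_name",
    "drug_role",
    "drug_start_date",
    "drug_indication",
    "event_pt",
    "event_onset_date",
    "outcome_codes",
]


def _fmt_date(d: date | None) -> str:
    return d.isoformat() if d is not None else ""


def _fmt_float(v: float | None) -> str:
    return repr(v) if v is not None else ""


def write_simple_csv(reports: Iterable[CaseReport], path: str | Path) -> None:
    """Write reports as one row per (report, drug, event) cross-product.

    The representation is lossless: reading the file back with
    :func:`read_reports` reproduces the report list exactly (report fields are
    repeated on each row; drug fields vary with the drug, the event term with
    the event).
    """
    rows = []
    for r in reports:
        out_codes = ";".join(sorted(_OUTC_TO_CODE[o] for o in r.outcomes))
        for d in r.drugs:
            for e in r.events:
                rows.append(
                    {
                        "case_id": r.case_id,
                        "receipt_date": _fmt_date(r.receipt_date),
                        "report_version": r.report_version,
                        "sex": r.sex.value,
                        "age_years": _fmt_float(r.age_years),
                        "weight_kg": _fmt_float(r.weight_kg),
                        "reporter": r.reporter.value,
                        "country": r.country or "",
                        "drug_name": d.name,
                        "drug_role": d.role.value,
                        "drug_start_date": _fmt_date(d.start_date),
                        "drug_indication": d.indication or "",
                        "event_pt": e,
                        "event_onset_date": _fmt_date(r.event_onset_date),
                        "outcome_codes": out_codes,
                    }
                )
    pd.DataFrame(rows, columns=SIMPLE_CSV_COLUMNS).to_csv(path, index=False)


def _read_simple_csv(paths: Sequence[Path]) -> list[CaseReport]:
    frames = []
    for p in paths:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        if "case_id" not in df.columns:
            raise FormatError(f"{p}: missing identifier column 'case_id'")
        frames.append(df)
    if not frames:
        return []
    df = pd.concat(frames, ignore_index=True)
    if df.empty:
        return []

    reports: list[CaseReport] = []
    for case_id, grp in df.groupby("case_id", sort=False):
        first = grp.iloc[0]
        drugs: list[DrugEntry] = []
        seen_drugs: set[tuple] = set()
        events: list[str] = []
        seen_events: set[str] = set()
        for _, row in grp.iterrows():
            name = str(row.get("drug_name", "")).strip()
            if name:
                key = (
                    name,
                    row.get("drug_role", ""),
                    row.get("drug_start_date", ""),
                    row.get("drug_indication", ""),
                )
                if key not in seen_drugs:
                    seen_drugs.add(key)
                    role = _DRUG_ROLE_CODES.get(
                        str(row.get("drug_role", "")).upper(),
                        None,
                    )
                    if role is None:
                        try:
                            role = DrugRole(str(row.get("drug_role", "")))
                        except ValueError:
                            role = DrugRole.PRIMARY_SUSPECT
                    drugs.append(
                        DrugEntry(
                            name=normalize_drug_name(name),
                            role=role,
                            start_date=parse_flexible_date(row.get("drug_start_date")),
                            indication=str(row.get("drug_indication", "")).strip() or None,
                        )
                    )
            pt = str(row.get("event_pt", "")).strip()
            if pt and normalize_term(pt) not in seen_events:
                seen_events.add(normalize_term(pt))
                events.append(pt)

        outcomes: set[Outcome] = set()
        for code in str(first.get("outcome_codes", "")).split(";"):
            code = code.strip().upper()
            if code in _OUTC_CODES:
                outcomes.add(_OUTC_CODES[code])

        sex_raw = str(first.get("sex", "")).strip().lower()
        try:
            sex = Sex(sex_raw) if sex_raw else Sex.UNKNOWN
        except ValueError:
            sex = {"f": Sex.FEMALE, "m": Sex.MALE}.get(sex_raw, Sex.UNKNOWN)
        rep_raw = str(first.get("reporter", "")).strip().lower()
        try:
            reporter = Reporter(rep_raw) if rep_raw else Reporter.UNKNOWN
        except ValueError:
            reporter = Reporter.UNKNOWN
        try:
            version = int(str(first.get("report_version", "0")) or 0)
        except ValueError:
            version = 0

        reports.append(
            CaseReport(
                case_id=str(case_id),
                receipt_date=parse_flexible_date(first.get("receipt_date")),
                report_version=version,
                sex=sex,
                age_years=_parse_float(first.get("age_years"), 0, 120),
                weight_kg=_parse_float(first.get("weight_kg"), 0, 400, closed_lo=False),
                reporter=reporter,
                country=str(first.get("country", "")).strip() or None,
                drugs=drugs,
                events=events,
                outcomes=frozenset(outcomes),
                event_onset_date=parse_flexible_date(first.get("event_onset_date")),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# faers_ascii dialect
# ---------------------------------------------------------------------------

_TABLE_TOKENS = ("DEMO", "DRUG", "REAC", "OUTC", "THER")


def _classify_faers_files(paths: Sequence[Path]) -> dict[str, list[Path]]:
    tables: dict[str, list[Path]] = {t: [] for t in _TABLE_TOKENS}
    for p in paths:
        upper = p.name.upper()
        for token in _TABLE_TOKENS:
            if token in upper:
                tables[token].append(p)
                break
    return tables


def _read_dollar(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing identifier column '{col}'")
    return df


def _age_to_years(val: object, cod: object) -> float | None:
    v = _parse_float(val, -1e9, 1e9)
    if v is None:
        return None
    factor = {
        "YR": 1.0,
        "": 1.0,
        "DEC": 10.0,
        "MON": 1 / 12.0,
        "WK": 1 / 52.1775,
        "DY": 1 / 365.25,
        "HR": 1 / 8766.0,
    }.get(str(cod).strip().upper())
    if factor is None:
        return None
    years = v * factor
    return years if 0 <= years <= 120 else None


def _weight_to_kg(val: object, cod: object) -> float | None:
    v = _parse_float(val, -1e9, 1e9)
    if v is None:
        return None
    factor = {"KG": 1.0, "": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}.get(
        str(cod).strip().upper()
    )
    if factor is None:
        return None
    kg = v * factor
    return kg if 0 < kg <= 400 else None


def _read_faers_ascii(paths: Sequence[Path]) -> list[CaseReport]:
    tables = _classify_faers_files(paths)
    if not tables["DEMO"]:
        raise FormatError("faers_ascii input requires a DEMO table")

    demo = pd.concat(
        [_read_dollar(p, ["primaryid"]) for p in tables["DEMO"]], ignore_index=True
    )
    drug = (
        pd.concat([_read_dollar(p, ["primaryid", "drugname"]) for p in tables["DRUG"]],
                  ignore_index=True)
        if tables["DRUG"]
        else pd.DataFrame(columns=["primaryid", "drugname"])
    )
    reac = (
        pd.concat([_read_dollar(p, ["primaryid", "pt"]) for p in tables["REAC"]],
                  ignore_index=True)
        if tables["REAC"]
        else pd.DataFrame(columns=["primaryid", "pt"])
    )
    outc = (
        pd.concat([_read_dollar(p, ["primaryid", "outc_cod"]) for p in tables["OUTC"]],
                  ignore_index=True)
        if tables["OUTC"]
        else pd.DataFrame(columns=["primaryid", "outc_cod"])
    )
    ther = (
        pd.concat([_read_dollar(p, ["primaryid", "start_dt"]) for p in tables["THER"]],
                  ignore_index=True)
        if tables["THER"]
        else pd.DataFrame(columns=["primaryid", "start_dt"])
    )

    # THER links to DRUG via (primaryid, drug_seq); fall back to report level.
    ther_by_seq: dict[tuple[str, str], date] = {}
    ther_by_report: dict[str, date] = {}
    seq_col = "dsg_drug_seq" if "dsg_drug_seq" in ther.columns else None
    for _, row in ther.iterrows():
        d = parse_flexible_date(row.get("start_dt"))
        if d is None:
            continue
        pid = str(row["primaryid"])
        if seq_col and str(row.get(seq_col, "")).strip():
            ther_by_seq[(pid, str(row[seq_col]).strip())] = d
        if pid not in ther_by_report or d < ther_by_report[pid]:
            ther_by_report[pid] = d

    drugs_by_report: dict[str, list[DrugEntry]] = {}
    for _, row in drug.iterrows():
        pid = str(row["primaryid"])
        name = normalize_drug_name(str(row.get("drugname", "")))
        if not name:
            continue
        seq = str(row.get("drug_seq", "")).strip()
        start = ther_by_seq.get((pid, seq)) if seq else None
        if start is None:
            start = ther_by_report.get(pid)
        indication = str(row.get("indi_pt", "")).strip() or None
        role = _DRUG_ROLE_CODES.get(str(row.get("role_cod", "")).strip().upper(),
                                    DrugRole.PRIMARY_SUSPECT)
        drugs_by_report.setdefault(pid, []).append(
            DrugEntry(name=name, role=role, start_date=start, indication=indication)
        )

    events_by_report: dict[str, list[str]] = {}
    for _, row in reac.iterrows():
        pid = str(row["primaryid"])
        pt = str(row.get("pt", "")).strip()
        if not pt:
            continue
        lst = events_by_report.setdefault(pid, [])
        if normalize_term(pt) not in {normalize_term(e) for e in lst}:
            lst.append(pt)

    outcomes_by_report: dict[str, set[Outcome]] = {}
    for _, row in outc.iterrows():
        code = str(row.get("outc_cod", "")).strip().upper()
        if code in _OUTC_CODES:
            outcomes_by_report.setdefault(str(row["primaryid"]), set()).add(_OUTC_CODES[code])

    reports: list[CaseReport] = []
    for _, row in demo.iterrows():
        pid = str(row["primaryid"])
        sex = {"F": Sex.FEMALE, "M": Sex.MALE}.get(
            str(row.get("sex", row.get("gndr_cod", ""))).strip().upper(), Sex.UNKNOWN
        )
        reporter = _OCCP_CODES.get(str(row.get("occp_cod", "")).strip().upper(),
                                   Reporter.UNKNOWN)
        try:
            version = int(str(row.get("caseversion", "0")).strip() or 0)
        except ValueError:
            version = 0
        reports.append(
            CaseReport(
                case_id=str(row.get("caseid", pid)).strip() or pid,
                receipt_date=parse_flexible_date(row.get("fda_dt")),
                report_version=version,
                sex=sex,
                age_years=_age_to_years(row.get("age"), row.get("age_cod", "")),
                weight_kg=_weight_to_kg(row.get("wt"), row.get("wt_cod", "")),
                reporter=reporter,
                country=str(row.get("reporter_country", "")).strip() or None,
                drugs=drugs_by_report.get(pid, []),
                events=events_by_report.get(pid, []),
                outcomes=frozenset(outcomes_by_report.get(pid, set())),
                event_onset_date=parse_flexible_date(row.get("event_dt")),
            )
        )
    return reports


def read_reports(
    paths: Sequence[str | Path] | str | Path, dialect: str = "simple_csv"
) -> list[CaseReport]:
    """Read case reports from files (or a directory) in the given dialect."""
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        path_list = sorted(p.iterdir()) if p.is_dir() else [p]
    else:
        path_list = [Path(p) for p in paths]
    for p in path_list:
        if not p.exists():
            raise FileNotFoundError(p)
    path_list = [p for p in path_list if p.is_file()]
    if dialect == "simple_csv":
        return _read_simple_csv(path_list)
    if dialect == "faers_ascii":
        return _read_faers_ascii(path_list)
    raise ValueError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# deduplication & curation
# ---------------------------------------------------------------------------

_DISTANT_PAST = date(1, 1, 1)


def deduplicate(reports: Sequence[CaseReport]) -> tuple[list[CaseReport], CurationLog]:
    """Keep one report per case_id: latest receipt date, then highest version.

    Remaining ties keep the first occurrence in input order. Output preserves
    the input order of the retained reports, so the operation is idempotent.
    """
    best: dict[str, tuple[date, int, int]] = {}
    keep: dict[str, CaseReport] = {}
    order: list[str] = []
    for i, r in enumerate(reports):
        key = (r.receipt_date or _DISTANT_PAST, r.report_version, -i)
        if r.case_id not in best:
            best[r.case_id] = key
            keep[r.case_id] = r
            order.append(r.case_id)
        elif key > best[r.case_id]:
            best[r.case_id] = key
            keep[r.case_id] = r
    out = [keep[cid] for cid in order]
    log = CurationLog(n_raw=len(reports), n_after_dedup=len(out), n_final=len(out))
    return out, log


def curate(
    reports: Sequence[CaseReport],
    target_event: str,
    rules: CurationRules = CurationRules(),
    log: CurationLog | None = None,
) -> tuple[list[CaseReport], list[CaseReport], CurationLog]:
    """Apply exclusion rules and split the corpus into cohort and background.

    Returns ``(cohort, background, log)`` where the cohort is every retained
    report whose event list contains ``target_event`` (case-insensitive exact
    preferred-term match, optionally widened by ``rules.synonyms``) and the
    background is every retained report (cohort included).
    """
    if not target_event or not target_event.strip():
        raise ValueError("target_event must be non-empty")
    if log is None:
        log = CurationLog(n_raw=len(reports), n_after_dedup=len(reports))
    background: list[CaseReport] = []
    for r in reports:
        if rules.require_drug and not r.drugs:
            log.n_excluded_nondrug += 1
            continue
        incomplete = rules.require_event and not r.events
        if r.report_year is not None and not (
            rules.year_min <= r.report_year <= rules.year_max
        ):
            incomplete = True
        if incomplete:
            log.n_excluded_incomplete += 1
            continue
        background.append(r)
    cohort = [r for r in background if r.has_event(target_event, rules.synonyms)]
    log.n_final = len(background)
    return cohort, background, log


def curate_pipeline(
    reports: Sequence[CaseReport],
    target_event: str,
    rules: CurationRules = CurationRules(),
) -> tuple[list[CaseReport], list[CaseReport], CurationLog]:
    """Deduplicate then curate, with a single combined log."""
    deduped, log = deduplicate(reports)
    return curate(deduped, target_event, rules, log=log)
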