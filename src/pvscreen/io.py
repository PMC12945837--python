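"""Readers and writers for case-report tables.

Two dialects are supported:

``flat_csv``
    One row per (report, drug, reaction) combination, UTF-8, header row.
    Columns: report_id, case_version, receipt_date, sex, age_years,
    age_unit, region, serious, drug_name, drug_role, therapy_start, pt,
    onset_date, outcome.  Dates are ISO-8601.

``faers_ascii``
    The quarterly FAERS extract layout: '$'-delimited DEMO / DRUG / REAC /
    THER / OUTC tables joined on ``primaryid``.  Partial dates (YYYY,
    YYYYMM) resolve to the first day of the period and are flagged
    imprecise.  Unknown extra columns are tolerated.
"""

from __future__ import annotations

import logging
import warnings
from datetime import date, datetime
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import FormatError
from .model import (
    CaseReport,
    DrugEntry,
    ReactionEntry,
    ReportStore,
    DRUG_ROLES,
    OUTCOMES,
    SEXES,
    REGIONS,
)

log = logging.getLogger(__name__)

FLAT_COLUMNS = [
    "report_id",
    "case_version",
    "receipt_date",
    "sex",
    "age_years",
    "age_unit",
    "region",
    "serious",
    "drug_name",
    "drug_role",
    "therapy_start",
    "pt",
    "onset_date",
    "outcome",
]

_MANDATORY_FLAT = {"report_id", "drug_name", "pt"}

_AGE_UNIT_FACTORS = {"yr": 1.0, "mon": 1.0 / 12.0, "dec": 10.0}

_FAERS_SEX = {"M": "male", "F": "female"}
_FAERS_ROLE = {"PS": "suspect", "SS": "suspect", "C": "concomitant", "I": "interacting"}
_FAERS_OUTCOME = {
    "RC": "recovered",
    "RE": "recovering",
    "NR": "not_recovered",
    "FA": "fatal",
    "DE": "fatal",
}


def parse_date(value, report_id: str = "?") -> tuple[Optional[date], bool]:
    """Parse an ISO or FAERS partial date.

    Returns (date, imprecise).  YYYY and YYYYMM resolve to the first day of
    the period with ``imprecise=True``.  Unparseable values warn at the
    record level and come back as unknown (None) rather than failing.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None, False
    s = str(value).strip()
    if not s or s.lower() in {"nan", "na", "unknown"}:
        return None, False
    if s.endswith(".0"):  # pandas float-cast of numeric date columns
        s = s[:-2]
    try:
        if len(s) == 4 and s.isdigit():
            return date(int(s), 1, 1), True
        if len(s) == 6 and s.isdigit():
            return date(int(s[:4]), int(s[4:6]), 1), True
        if len(s) == 8 and s.isdigit():
            return datetime.strptime(s, "%Y%m%d").date(), False
        return date.fromisoformat(s), False
    except ValueError:
        warnings.warn(
            f"report {report_id}: unparseable date {s!r}; treated as unknown",
            stacklevel=2,
        )
        return None, False


def _norm_sex(value) -> str:
    if value is None or pd.isna(value):
        return "unknown"
    s = str(value).strip().lower()
    if s in SEXES:
        return s
    return _FAERS_SEX.get(str(value).strip().upper(), "unknown")


def _norm_region(value) -> str:
    if value is None or pd.isna(value):
        return "unknown"
    s = str(value).strip().lower()
    return s if s in REGIONS else "unknown"


def _norm_age(value, unit) -> Optional[float]:
    if value is None or pd.isna(value):
        return None
    try:
        age = float(value)
    except (TypeError, ValueError):
        return None
    factor = _AGE_UNIT_FACTORS.get(str(unit).strip().lower(), 1.0) if unit is not None and not pd.isna(unit) else 1.0
    age *= factor
    if not (0 <= age <= 120):
        warnings.warn(f"age {age} out of [0, 120]; treated as unknown", stacklevel=2)
        return None
    return age


def _norm_bool(value) -> bool:
    if value is None or pd.isna(value):
        return False
    return str(value).strip().lower() in {"1", "true", "yes", "y", "t"}


def read_reports(path, dialect: str = "flat_csv") -> ReportStore:
    """Read a case-report table into a :class:`ReportStore`.

    Records with missing sex/age/dates get the explicit unknown value and
    are never silently dropped.
    """
    if dialect == "flat_csv":
        return _read_flat_csv(Path(path))
    if dialect == "faers_ascii":
        return _read_faers_ascii(Path(path))
    raise FormatError(f"unknown dialect {dialect!r}")


def _read_flat_csv(path: Path) -> ReportStore:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype=str)
    missing = _MANDATORY_FLAT - set(frame.columns)
    if missing:
        raise FormatError(
            f"flat_csv {path} missing mandatory column(s): {', '.join(sorted(missing))}"
        )
    for col in FLAT_COLUMNS:
        if col not in frame.columns:
            frame[col] = None

    reports: list[CaseReport] = []
    for (rid, ver), group in frame.groupby(
        ["report_id", frame["case_version"].fillna("1")], sort=True
    ):
        first = group.iloc[0]
        receipt, _ = parse_date(first["receipt_date"], rid)
        drugs: dict[tuple, DrugEntry] = {}
        reactions: dict[tuple, ReactionEntry] = {}
        for _, row in group.iterrows():
            dname = row["drug_name"]
            if dname is not None and not pd.isna(dname) and str(dname).strip():
                role = str(row["drug_role"]).strip().lower() if row["drug_role"] is not None and not pd.isna(row["drug_role"]) else "suspect"
                if role not in DRUG_ROLES:
                    role = "suspect"
                tstart, imprecise = parse_date(row["therapy_start"], rid)
                entry = DrugEntry(str(dname).strip(), role, tstart, imprecise)
                drugs.setdefault((entry.drug_name, entry.role, entry.therapy_start), entry)
            pt = row["pt"]
            if pt is not None and not pd.isna(pt) and str(pt).strip():
                onset, _ = parse_date(row["onset_date"], rid)
                outcome = str(row["outcome"]).strip().lower() if row["outcome"] is not None and not pd.isna(row["outcome"]) else "unknown"
                if outcome not in OUTCOMES:
                    outcome = "unknown"
                entry = ReactionEntry(str(pt).strip(), onset, outcome)
                reactions.setdefault((entry.pt, entry.onset_date, entry.outcome), entry)
        if not drugs or not reactions:
            warnings.warn(f"report {rid}: no drug or no reaction; skipped", stacklevel=2)
            continue
        reports.append(
            CaseReport(
                report_id=str(rid),
                case_version=int(float(ver)),
                receipt_date=receipt,
                sex=_norm_sex(first["sex"]),
                age_years=_norm_age(first["age_years"], first["age_unit"]),
                region=_norm_region(first["region"]),
                serious=_norm_bool(first["serious"]),
                drugs=tuple(drugs.values()),
                reactions=tuple(reactions.values()),
            )
        )
    return ReportStore(reports, provenance=str(path))


def write_reports(store: ReportStore, path) -> None:
    """Write a store as flat_csv (the round-trip inverse of read_reports).

    Every (drug, reaction) combination of a report becomes one row, so the
    reader's grouping reconstructs the store field-for-field.
    """
    rows = []
    for r in store.reports:
        for d in r.drugs:
            for x in r.reactions:
                rows.append(
                    {
                        "report_id": r.report_id,
                        "case_version": r.case_version,
                        "receipt_date": r.receipt_date.isoformat() if r.receipt_date else "",
                        "sex": r.sex,
                        "age_years": "" if r.age_years is None else r.age_years,
                        "age_unit": "yr",
                        "region": r.region,
                        "serious": int(r.serious),
                        "drug_name": d.drug_name,
                        "drug_role": d.role,
                        "therapy_start": d.therapy_start.isoformat() if d.therapy_start else "",
                        "pt": x.pt,
                        "onset_date": x.onset_date.isoformat() if x.onset_date else "",
                        "outcome": x.outcome,
                    }
                )
    pd.DataFrame(rows, columns=FLAT_COLUMNS).to_csv(path, index=False)


# ---- FAERS quarterly ASCII ----------------------------------------------


def _read_faers_table(path: Path, mandatory: set[str]) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="$", dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = mandatory - set(frame.columns)
    if missing:
        raise FormatError(
            f"{path.name} missing mandatory column(s): {', '.join(sorted(missing))}"
        )
    return frame


def _read_faers_ascii(root: Path) -> ReportStore:
    """Read a directory of DEMO/DRUG/REAC(/THER/OUTC) '$'-delimited tables."""
    if root.is_file():
        raise FormatError("faers_ascii expects a directory of DEMO/DRUG/REAC tables")

    def find(stem: str) -> Optional[Path]:
        hits = sorted(root.glob(f"{stem}*.txt")) + sorted(root.glob(f"{stem}*.TXT"))
        return hits[0] if hits else None

    demo_p, drug_p, reac_p = find("DEMO") or find("demo"), find("DRUG") or find("drug"), find("REAC") or find("reac")
    for name, p in (("DEMO", demo_p), ("DRUG", drug_p), ("REAC", reac_p)):
        if p is None:
            raise FormatError(f"faers_ascii: {name} table not found under {root}")

    demo = _read_faers_table(demo_p, {"primaryid"})
    drug = _read_faers_table(drug_p, {"primaryid", "drugname"})
    reac = _read_faers_table(reac_p, {"primaryid", "pt"})
    ther_p, outc_p = find("THER") or find("ther"), find("OUTC") or find("outc")
    ther = _read_faers_table(ther_p, {"primaryid"}) if ther_p else None
    outc = _read_faers_table(outc_p, {"primaryid"}) if outc_p else None

    ther_start: dict[str, tuple[Optional[date], bool]] = {}
    if ther is not None and "start_dt" in ther.columns:
        for _, row in ther.iterrows():
            pid = row["primaryid"]
            if pid not in ther_start:
                ther_start[pid] = parse_date(row["start_dt"], pid)
    serious_ids = set()
    if outc is not None and "outc_cod" in outc.columns:
        serious_ids = set(outc["primaryid"])

    drugs_by_id: dict[str, list[DrugEntry]] = {}
    for _, row in drug.iterrows():
        pid = row["primaryid"]
        name = row["drugname"]
        if name is None or pd.isna(name) or not str(name).strip():
            continue
        role = _FAERS_ROLE.get(str(row.get("role_cod", "")).strip().upper(), "suspect")
        tstart, imprecise = ther_start.get(pid, (None, False))
        drugs_by_id.setdefault(pid, []).append(
            DrugEntry(str(name).strip(), role, tstart, imprecise)
        )

    reac_by_id: dict[str, list[ReactionEntry]] = {}
    for _, row in reac.iterrows():
        pid = row["primaryid"]
        pt = row["pt"]
        if pt is None or pd.isna(pt) or not str(pt).strip():
            continue
        reac_by_id.setdefault(pid, []).append(ReactionEntry(str(pt).strip()))

    reports = []
    for _, row in demo.iterrows():
        pid = row["primaryid"]
        drugs = drugs_by_id.get(pid)
        reactions = reac_by_id.get(pid)
        if not drugs or not reactions:
            log.warning("primaryid %s lacks drug or reaction lines; skipped", pid)
            continue
        receipt, _ = parse_date(row.get("fda_dt"), pid)
        caseversion = row.get("caseversion")
        try:
            version = int(float(caseversion)) if caseversion is not None and not pd.isna(caseversion) else 1
        except (TypeError, ValueError):
            version = 1
        reports.append(
            CaseReport(
                report_id=str(row.get("caseid", pid)),
                case_version=max(version, 1),
                receipt_date=receipt,
                sex=_norm_sex(row.get("sex")),
                age_years=_norm_age(row.get("age"), row.get("age_cod")),
                region="unknown",
                serious=pid in serious_ids,
                drugs=tuple(drugs),
                reactions=tuple(reactions),
            )
        )
    return ReportStore(reports, provenance=str(root))
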