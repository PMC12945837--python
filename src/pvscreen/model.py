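"""Core data model for spontaneous adverse-event reports.

A spontaneous reporting system (SRS) such as FAERS or VigiBase collects
individual case safety reports: one patient, one or more suspected or
concomitant drugs, and one or more adverse reactions coded as MedDRA
preferred terms (PTs).  The types here are deliberately plain containers;
all analysis operates on pandas frames derived from them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError, MappingError

SEXES = ("male", "female", "unknown")
REGIONS = ("americas", "europe", "asia", "oceania", "africa", "unknown")
DRUG_ROLES = ("suspect", "concomitant", "interacting")
OUTCOMES = ("recovered", "recovering", "not_recovered", "fatal", "unknown")

_PUNCT_RE = re.compile(r"[^a-z0-9 ]+")
_WS_RE = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Canonical form of a free-text drug name.

    FAERS drug names are free text (brand names, generics, typos, dose
    decorations); lower-case, strip punctuation, collapse whitespace.
    """
    s = _PUNCT_RE.sub(" ", name.strip().lower())
    return _WS_RE.sub(" ", s).strip()


class SynonymTable:
    """User-extensible brand<->generic synonym map.

    Every synonym resolves to one canonical (generic) name.  Lookup is
    performed on normalized names, so ``BRIUMVI`` and ``briumvi.`` both
    resolve to ``ublituximab`` once registered.
    """

    def __init__(self, synonyms: Optional[Mapping[str, str]] = None):
        self._map: dict[str, str] = {}
        if synonyms:
            for alias, canonical in synonyms.items():
                self.add(alias, canonical)

    def add(self, alias: str, canonical: str) -> None:
        self._map[normalize_drug_name(alias)] = normalize_drug_name(canonical)

    def resolve(self, name: str) -> str:
        norm = normalize_drug_name(name)
        return self._map.get(norm, norm)

    @classmethod
    def from_csv(cls, path) -> "SynonymTable":
        frame = pd.read_csv(path)
        if not {"alias", "canonical"}.issubset(frame.columns):
            raise ConfigError("synonym table needs columns: alias, canonical")
        return cls(dict(zip(frame["alias"], frame["canonical"])))


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug line of a case report."""

    drug_name: str
    role: str = "suspect"
    therapy_start: Optional[date] = None
    date_imprecise: bool = False

    def __post_init__(self):
        if not self.drug_name:
            raise ConfigError("drug_name must be non-empty")
        if self.role not in DRUG_ROLES:
            raise ConfigError(f"drug role {self.role!r} not in {DRUG_ROLES}")


@dataclass(frozen=True, slots=True)
class ReactionEntry:
    """One reaction (PT) line of a case report."""

    pt: str
    onset_date: Optional[date] = None
    outcome: str = "unknown"

    def __post_init__(self):
        if not self.pt:
            raise ConfigError("pt must be non-empty")
        if self.outcome not in OUTCOMES:
            raise ConfigError(f"outcome {self.outcome!r} not in {OUTCOMES}")


@dataclass(frozen=True, slots=True)
class CaseReport:
    """One spontaneous report after joining its demographic, drug and
    reaction lines.

    ``weight`` is 1 for ordinary reports; aggregated pseudo-reports used to
    replay large published contingency tables carry an integer weight, and
    every counting operation in the package sums weights.
    """

    report_id: str
    case_version: int = 1
    receipt_date: Optional[date] = None
    sex: str = "unknown"
    age_years: Optional[float] = None
    region: str = "unknown"
    serious: bool = False
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[ReactionEntry, ...] = ()
    weight: int = 1

    def __post_init__(self):
        if self.case_version < 1:
            raise ConfigError("case_version must be >= 1")
        if self.sex not in SEXES:
            raise ConfigError(f"sex {self.sex!r} not in {SEXES}")
        if self.region not in REGIONS:
            raise ConfigError(f"region {self.region!r} not in {REGIONS}")
        if not self.drugs or not self.reactions:
            raise ConfigError("a report needs at least one drug and one reaction")
        if self.age_years is not None and not (0 <= self.age_years <= 120):
            raise ConfigError("age_years out of [0, 120]")
        if self.weight < 1:
            raise ConfigError("weight must be a positive integer")

    def distinct_pts(self) -> tuple[str, ...]:
        """Reaction PTs de-duplicated within the report, order preserved."""
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.pt, None)
        return tuple(seen)

    def drug_names(self, synonyms: Optional[SynonymTable] = None) -> frozenset[str]:
        if synonyms is None:
            return frozenset(normalize_drug_name(d.drug_name) for d in self.drugs)
        return frozenset(synonyms.resolve(d.drug_name) for d in self.drugs)


class MedDRAHierarchy:
    """PT -> primary SOC mapping (user supplied; MedDRA itself is licensed).

    The mapping must be total over every PT that reaches a screen: a lookup
    of an unmapped PT raises :class:`MappingError`.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return pt in self._map

    def soc(self, pt: str) -> str:
        try:
            return self._map[pt]
        except KeyError:
            raise MappingError([pt]) from None

    def socs(self, pts: Iterable[str]) -> list[str]:
        missing = [p for p in pts if p not in self._map]
        if missing:
            raise MappingError(set(missing))
        return [self._map[p] for p in pts]

    def pts_of_soc(self, soc: str) -> frozenset[str]:
        return frozenset(p for p, s in self._map.items() if s == soc)

    @classmethod
    def from_csv(cls, path) -> "MedDRAHierarchy":
        frame = pd.read_csv(path)
        if not {"pt", "soc"}.issubset(frame.columns):
            raise ConfigError("pt2soc mapping needs columns: pt, soc")
        return cls(dict(zip(frame["pt"], frame["soc"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(sorted(self._map.items()), columns=["pt", "soc"]).to_csv(
            path, index=False
        )


@dataclass
class ReportStore:
    """A collection of case reports plus a provenance label."""

    reports: list[CaseReport] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def total_weight(self) -> int:
        return sum(r.weight for r in self.reports)

    def replace_reports(self, reports: Sequence[CaseReport]) -> "ReportStore":
        return ReportStore(list(reports), provenance=self.provenance)

    # ---- derived frames -------------------------------------------------

    def report_frame(self) -> pd.DataFrame:
        """One row per report: demographics and weight."""
        rows = [
            (r.report_id, r.sex, r.age_years, r.serious, r.weight)
            for r in self.reports
        ]
        return pd.DataFrame(
            rows, columns=["report_id", "sex", "age_years", "serious", "weight"]
        )

    def event_frame(self) -> pd.DataFrame:
        """One row per (report, distinct PT) event record.

        This is the counting unit of the disproportionality tables: a
        report listing the same PT twice contributes one record for it.
        """
        ids, sexes, ages, pts, weights = [], [], [], [], []
        for r in self.reports:
            for pt in r.distinct_pts():
                ids.append(r.report_id)
                sexes.append(r.sex)
                ages.append(r.age_years)
                pts.append(pt)
                weights.append(r.weight)
        return pd.DataFrame(
            {
                "report_id": ids,
                "sex": sexes,
                "age_years": ages,
                "pt": pts,
                "weight": weights,
            }
        )

    def observed_pts(self) -> set[str]:
        out: set[str] = set()
        for r in self.reports:
            out.update(r.distinct_pts())
        return out


# ---- deduplication and selection ---------------------------------------


def _content_key(report: CaseReport):
    return (
        report.sex,
        report.age_years,
        frozenset(normalize_drug_name(d.drug_name) for d in report.drugs),
        frozenset(r.pt for r in report.reactions),
        report.receipt_date,
    )


def deduplicate(store: ReportStore) -> ReportStore:
    """Drop superseded case versions, then collapse exact-content duplicates.

    Rule 1 (version): for reports sharing ``report_id`` keep the highest
    ``case_version``; ties broken by latest ``receipt_date``.
    Rule 2 (content): reports with distinct ids but identical
    (sex, age, drug-name set, PT set, receipt date) collapse to the one
    with the lexicographically smallest ``report_id``.

    Idempotent, never increases the report count.
    """
    best: dict[str, CaseReport] = {}
    for r in store.reports:
        cur = best.get(r.report_id)
        if cur is None:
            best[r.report_id] = r
            continue
        key_new = (r.case_version, r.receipt_date or date.min)
        key_cur = (cur.case_version, cur.receipt_date or date.min)
        if key_new > key_cur:
            best[r.report_id] = r

    by_content: dict[tuple, CaseReport] = {}
    for r in best.values():
        key = _content_key(r)
        cur = by_content.get(key)
        if cur is None or r.report_id < cur.report_id:
            by_content[key] = r

    kept = sorted(by_content.values(), key=lambda r: r.report_id)
    return store.replace_reports(kept)


def select_drug_reports(
    store: ReportStore,
    drug: str,
    roles: Iterable[str] = DRUG_ROLES,
    synonyms: Optional[SynonymTable] = None,
) -> ReportStore:
    """Reports containing at least one entry for ``drug`` in one of ``roles``.

    Name matching is case-insensitive after normalization and goes through
    the synonym table, so brand names select the same reports as the
    generic.
    """
    if not drug:
        raise ConfigError("drug must be non-empty")
    roles = frozenset(roles)
    syn = synonyms or SynonymTable()
    target = syn.resolve(drug)
    kept = [
        r
        for r in store.reports
        if any(syn.resolve(d.drug_name) == target and d.role in roles for d in r.drugs)
    ]
    return store.replace_reports(kept)


def exposed_report_ids(
    store: ReportStore,
    drugs: Sequence[str],
    roles: Iterable[str] = DRUG_ROLES,
    synonyms: Optional[SynonymTable] = None,
) -> frozenset[str]:
    """Ids of reports containing *all* of ``drugs`` (each in an allowed role)."""
    roles = frozenset(roles)
    syn = synonyms or SynonymTable()
    targets = [syn.resolve(d) for d in drugs]
    out = []
    for r in store.reports:
        names = frozenset(
            syn.resolve(d.drug_name) for d in r.drugs if d.role in roles
        )
        if all(t in names for t in targets):
            out.append(r.report_id)
    return frozenset(out)
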