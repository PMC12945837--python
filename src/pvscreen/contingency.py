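"""Two-by-two contingency tables for (exposure, event) pairs.

The disproportionality table compares the target exposure's reporting of a
target event against the background of all other exposures:

                     target event    other events    total
    target drug           a               b           a+b
    other drugs           c               d           c+d

The default counting unit is the *event record* — one (report, distinct PT)
pair — matching how SRS databases tally "AEs" as opposed to reports.  With
``unit="report"`` each report contributes at most one count per cell
(b and d then count reports *without* the event).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MappingError
from .model import MedDRAHierarchy, ReportStore

AGE_BINS = ("<18", "18-44", "45-64", ">=65")
_AGE_EDGES = {"<18": (0.0, 18.0), "18-44": (18.0, 45.0), "45-64": (45.0, 65.0), ">=65": (65.0, 121.0)}


def age_bin(age_years: Optional[float]) -> Optional[str]:
    """Assign an age in years to the stratification bins.

    Boundaries are [18, 44], [45, 64], [65, inf) with fractional ages
    resolved downward: 44.9 is still 18-44.  None stays None (unknown).
    """
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return None
    for label, (lo, hi) in _AGE_EDGES.items():
        if lo <= age_years < hi:
            return label
    return None


@dataclass(frozen=True, slots=True)
class Stratum:
    """A demographic slice: sex and/or age-group restriction."""

    sex: str = "any"
    age: str = "any"
    label: str = ""

    def __post_init__(self):
        if self.sex not in {"male", "female", "unknown", "any"}:
            raise ConfigError(f"bad sex filter {self.sex!r}")
        if self.age not in set(AGE_BINS) | {"any", "unknown"}:
            raise ConfigError(f"bad age filter {self.age!r}")
        if not self.label:
            object.__setattr__(self, "label", self.describe())

    def describe(self) -> str:
        parts = []
        if self.sex != "any":
            parts.append(f"sex={self.sex}")
        if self.age != "any":
            parts.append(f"age={self.age}")
        return ", ".join(parts) or "overall"

    def is_trivial(self) -> bool:
        return self.sex == "any" and self.age == "any"


OVERALL = Stratum()


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """a/b/c/d counts for one (exposure, event) pair in one stratum."""

    a: int
    b: int
    c: int
    d: int
    exposure: str = ""
    event: str = ""
    stratum: str = "overall"
    unit: str = "record"

    def __post_init__(self):
        for cell, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0:
                raise ConfigError(f"cell {cell} negative: {v}")
        # an empty stratum yields the all-zero degenerate table; statistics
        # on it are undefined but construction is allowed

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when the exposure margin is empty in this stratum."""
        return self.a + self.b == 0

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _stratum_mask(events: pd.DataFrame, stratum: Stratum) -> pd.Series:
    mask = pd.Series(True, index=events.index)
    if stratum.sex != "any":
        mask &= events["sex"] == stratum.sex
    if stratum.age != "any":
        bins = events["age_years"].map(age_bin)
        if stratum.age == "unknown":
            mask &= bins.isna()
        else:
            mask &= bins == stratum.age
    return mask


def _event_pts(
    event: str, level: str, hierarchy: Optional[MedDRAHierarchy]
) -> Optional[frozenset[str]]:
    """PT set matched by the event descriptor; None means 'match by name'."""
    if level == "pt":
        return frozenset([event])
    if level == "soc":
        if hierarchy is None:
            raise ConfigError("SOC-level events need a PT->SOC hierarchy")
        return hierarchy.pts_of_soc(event)
    raise ConfigError(f"event level must be 'pt' or 'soc', got {level!r}")


def build_table(
    store: ReportStore,
    exposed_ids: frozenset[str],
    event: str,
    stratum: Stratum = OVERALL,
    unit: str = "record",
    level: str = "pt",
    hierarchy: Optional[MedDRAHierarchy] = None,
    exposure_label: str = "",
) -> ContingencyTable:
    """Build the 2x2 table for one event.

    ``exposed_ids`` is the set of report ids forming the target exposure
    (see :func:`pvscreen.model.exposed_report_ids`); all other reports are
    the comparator.  SOC-level events roll up every PT mapping to the SOC;
    a screened PT absent from the hierarchy raises :class:`MappingError`.
    An empty stratum yields a degenerate all-zero-margin table.
    """
    if unit not in {"record", "report"}:
        raise ConfigError(f"unit must be 'record' or 'report', got {unit!r}")
    events = store.event_frame()
    if events.empty:
        raise ConfigError("store has no reports")
    if level == "soc" and hierarchy is not None:
        missing = {p for p in set(events["pt"]) if p not in hierarchy}
        if missing:
            raise MappingError(missing)
    pts = _event_pts(event, level, hierarchy)

    mask = _stratum_mask(events, stratum)
    sub = events[mask]
    exp = sub["report_id"].isin(exposed_ids)
    hit = sub["pt"].isin(pts)
    w = sub["weight"]

    if unit == "record":
        a = int(w[exp & hit].sum())
        b = int(w[exp & ~hit].sum())
        c = int(w[~exp & hit].sum())
        d = int(w[~exp & ~hit].sum())
    else:
        per_report = sub.groupby("report_id").agg(
            weight=("weight", "first"), hit=("pt", lambda s: s.isin(pts).any())
        )
        per_report["exp"] = per_report.index.isin(exposed_ids)
        a = int(per_report.weight[per_report.exp & per_report.hit].sum())
        b = int(per_report.weight[per_report.exp & ~per_report.hit].sum())
        c = int(per_report.weight[~per_report.exp & per_report.hit].sum())
        d = int(per_report.weight[~per_report.exp & ~per_report.hit].sum())
    return ContingencyTable(
        a, b, c, d,
        exposure=exposure_label,
        event=event,
        stratum=stratum.label,
        unit=unit,
    )


def build_all_pt_tables(
    store: ReportStore,
    exposed_ids: frozenset[str],
    stratum: Stratum = OVERALL,
    min_a: int = 0,
    unit: str = "record",
    exposure_label: str = "",
) -> list[tuple[str, ContingencyTable]]:
    """One table per PT with a >= ``min_a``.

    All returned tables share the same margins (a+b, c+d) within the
    stratum.  Sorted by a descending, then PT ascending.
    """
    if min_a < 0:
        raise ConfigError("min_a must be >= 0")
    frame = pt_count_frame(store, exposed_ids, stratum, unit=unit)
    out = []
    for row in frame.itertuples():
        if row.a < min_a:
            continue
        out.append(
            (
                row.pt,
                ContingencyTable(
                    int(row.a), int(row.b), int(row.c), int(row.d),
                    exposure=exposure_label, event=row.pt,
                    stratum=stratum.label, unit=unit,
                ),
            )
        )
    out.sort(key=lambda item: (-item[1].a, item[0]))
    return out


def pt_count_frame(
    store: ReportStore,
    exposed_ids: frozenset[str],
    stratum: Stratum = OVERALL,
    unit: str = "record",
) -> pd.DataFrame:
    """Vectorized a/b/c/d per observed PT (columns pt, a, b, c, d)."""
    if unit not in {"record", "report"}:
        raise ConfigError(f"unit must be 'record' or 'report', got {unit!r}")
    events = store.event_frame()
    if events.empty:
        return pd.DataFrame(columns=["pt", "a", "b", "c", "d"])
    sub = events[_stratum_mask(events, stratum)]
    if sub.empty:
        return pd.DataFrame(columns=["pt", "a", "b", "c", "d"])
    exp = sub["report_id"].isin(exposed_ids).to_numpy()
    w = sub["weight"].to_numpy()

    grouped = pd.DataFrame(
        {"pt": sub["pt"].to_numpy(), "wa": np.where(exp, w, 0), "wc": np.where(exp, 0, w)}
    ).groupby("pt", sort=True).sum()

    if unit == "record":
        total_exp = int(grouped["wa"].sum())
        total_non = int(grouped["wc"].sum())
        a = grouped["wa"].astype(int)
        c = grouped["wc"].astype(int)
        b = total_exp - a
        d = total_non - c
    else:
        reports = sub.groupby("report_id")["weight"].first()
        rep_exp = reports.index.isin(exposed_ids)
        total_exp = int(reports[rep_exp].sum())
        total_non = int(reports[~rep_exp].sum())
        # a report counts once per PT it lists, so per-PT report counts equal
        # record counts (PTs are distinct within a report); the complements
        # count reports without the PT.
        a = grouped["wa"].astype(int)
        c = grouped["wc"].astype(int)
        b = total_exp - a
        d = total_non - c
    return pd.DataFrame(
        {"pt": grouped.index, "a": a.to_numpy(), "b": b.to_numpy(), "c": c.to_numpy(), "d": d.to_numpy()}
    ).reset_index(drop=True)
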