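"""Sex/age-stratified screens and time-to-onset (TTO) summaries.

Stratified screening restricts both the exposure and the comparator to one
demographic slice before building the tables, so each stratum's screen is
a self-contained disproportionality analysis.  Reports with the relevant
field unknown are excluded from that stratification (but remain in the
overall screen).

Time to onset is the number of days from the first therapy start of the
matching drug entries to the reaction's onset date.  Spontaneous reports
carry no risk-set information, so the per-sex cumulative curves are plain
empirical CDFs over reports with known TTO, not censoring-adjusted
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contingency import OVERALL, Stratum
from .model import MedDRAHierarchy, ReportStore, SynonymTable
from .screening import ScreenResult, screen_pt
from .stats import BCPNNPriors, ThresholdConfig

TTO_BINS = ("0-30", "31-60", "61-90", "91-180", "181-360", ">360")
_TTO_EDGES = (0, 31, 61, 91, 181, 361)

DEFAULT_STRATA = (
    Stratum(sex="male"),
    Stratum(sex="female"),
    Stratum(age="<18"),
    Stratum(age="18-44"),
    Stratum(age="45-64"),
    Stratum(age=">=65"),
)


def stratified_screen(
    store: ReportStore,
    exposed_ids: frozenset[str],
    hierarchy: MedDRAHierarchy,
    thresholds: ThresholdConfig = ThresholdConfig(),
    priors: BCPNNPriors = BCPNNPriors(),
    strata: Sequence[Stratum] = DEFAULT_STRATA,
    rule: str = "ror & prr",
    unit: str = "record",
    exposure_label: str = "",
) -> tuple[dict[str, ScreenResult], pd.DataFrame]:
    """Run the PT screen within each stratum.

    Returns (per-stratum results keyed by stratum label, cross-stratum
    comparison frame).  The comparison frame has one row per PT flagged
    positive in at least one stratum and one boolean column per stratum,
    making stratum-specific signals (positive in A, not in B) directly
    readable.
    """
    results: dict[str, ScreenResult] = {}
    for stratum in strata:
        results[stratum.label] = screen_pt(
            store, exposed_ids, hierarchy, thresholds, priors,
            stratum=stratum, rule=rule, unit=unit, exposure_label=exposure_label,
        )
    pts: dict[str, dict[str, bool]] = {}
    for label, res in results.items():
        for pt in res.positive["pt"]:
            pts.setdefault(pt, {})[label] = True
    rows = []
    for pt in sorted(pts):
        row = {"pt": pt}
        for stratum in strata:
            row[stratum.label] = pts[pt].get(stratum.label, False)
        rows.append(row)
    comparison = pd.DataFrame(rows, columns=["pt"] + [s.label for s in strata])
    return results, comparison


def sex_contrast(
    store: ReportStore,
    exposed_ids: frozenset[str],
    min_a: int = 3,
    z: float = 1.96,
) -> pd.DataFrame:
    """Female-vs-male event contrast *within* the exposure's own reports.

    Reuses the odds-ratio machinery with 'female' as the exposure row:
    a = female records of the PT, b = other female records, c/d the male
    analogues.  Complements the per-stratum screens when asking which
    events skew by sex among the drug's reports themselves.
    """
    from .contingency import pt_count_frame
    from .stats import ror_arrays

    exposed = store.replace_reports([r for r in store if r.report_id in exposed_ids])
    female_ids = frozenset(r.report_id for r in exposed if r.sex == "female")
    known = exposed.replace_reports([r for r in exposed if r.sex in ("female", "male")])
    counts = pt_count_frame(known, female_ids)
    counts = counts[counts["a"] + counts["c"] >= min_a]
    if counts.empty:
        return pd.DataFrame(columns=["pt", "female_records", "male_records", "or", "or_lo", "or_hi"])
    a, b, c, d = (counts[k].to_numpy() for k in "abcd")
    orr, lo, hi = ror_arrays(a, b, c, d, z)
    return pd.DataFrame(
        {"pt": counts["pt"], "female_records": a, "male_records": c,
         "or": orr, "or_lo": lo, "or_hi": hi}
    ).sort_values("or", ascending=False, kind="mergesort").reset_index(drop=True)


# ---- time to onset -------------------------------------------------------


@dataclass(frozen=True, slots=True)
class TTORecord:
    """One report's time to onset for the screened event."""

    report_id: str
    days: Optional[int]
    sex: str = "unknown"


@dataclass
class TTOSummary:
    """Binned TTO distribution, median, missingness and per-sex ECDFs."""

    records: list[TTORecord]
    bin_counts: dict[str, int]
    bin_proportions: dict[str, float]
    median_days: Optional[float]
    unknown_fraction: float
    n_known: int
    n_negative_excluded: int
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": list(TTO_BINS),
                "count": [self.bin_counts[b] for b in TTO_BINS],
                "proportion": [self.bin_proportions[b] for b in TTO_BINS],
            }
        )


def _tto_bin(days: int) -> str:
    if days >= _TTO_EDGES[-1]:
        return TTO_BINS[-1]
    idx = np.searchsorted(_TTO_EDGES, days, side="right") - 1
    return TTO_BINS[idx]


def tto_records(
    store: ReportStore,
    drug: str,
    event: Optional[str] = None,
    roles=("suspect", "concomitant", "interacting"),
    synonyms: Optional[SynonymTable] = None,
) -> tuple[list[TTORecord], int]:
    """Per-report TTO for the drug's earliest therapy start.

    ``event=None`` uses each report's earliest matching reaction onset over
    all its PTs; otherwise only the named PT.  Reports lacking either date
    yield ``days=None``.  Negative differences are implausible (onset
    before therapy) and are excluded, returned as a count.
    """
    syn = synonyms or SynonymTable()
    target = syn.resolve(drug)
    roles = frozenset(roles)
    records: list[TTORecord] = []
    n_negative = 0
    for r in store:
        matching = [
            d for d in r.drugs
            if d.role in roles and syn.resolve(d.drug_name) == target
        ]
        if not matching:
            continue
        if event is not None and not any(x.pt == event for x in r.reactions):
            continue
        starts = [d.therapy_start for d in matching if d.therapy_start]
        onsets = [
            x.onset_date
            for x in r.reactions
            if (event is None or x.pt == event) and x.onset_date
        ]
        if not starts or not onsets:
            records.append(TTORecord(r.report_id, None, r.sex))
            continue
        days = (min(onsets) - min(starts)).days
        if days < 0:
            n_negative += 1
            continue
        records.append(TTORecord(r.report_id, int(days), r.sex))
    return records, n_negative


def tto_summary(
    store: ReportStore,
    drug: str,
    event: Optional[str] = None,
    roles=("suspect", "concomitant", "interacting"),
    synonyms: Optional[SynonymTable] = None,
) -> TTOSummary:
    """Summarize time to onset for the exposure (and optionally one PT).

    The median is the lower median for even counts; unknown TTO is
    reported as a fraction, never imputed.
    """
    records, n_negative = tto_records(store, drug, event, roles, synonyms)
    known = sorted(r.days for r in records if r.days is not None)
    n_known = len(known)
    unknown_fraction = (
        (len(records) - n_known) / len(records) if records else 0.0
    )
    bin_counts = {b: 0 for b in TTO_BINS}
    for d in known:
        bin_counts[_tto_bin(d)] += 1
    bin_props = {
        b: (bin_counts[b] / n_known if n_known else 0.0) for b in TTO_BINS
    }
    median = float(known[(n_known - 1) // 2]) if n_known else None

    curves: dict[str, pd.DataFrame] = {}
    for sex in ("female", "male"):
        vals = sorted(r.days for r in records if r.days is not None and r.sex == sex)
        if not vals:
            continue
        days_arr = np.asarray(vals)
        uniq, counts = np.unique(days_arr, return_counts=True)
        cum = np.cumsum(counts) / len(vals)
        curves[sex] = pd.DataFrame({"days": uniq, "cumulative": cum})
    return TTOSummary(
        records=records,
        bin_counts=bin_counts,
        bin_proportions=bin_props,
        median_days=median,
        unknown_fraction=unknown_fraction,
        n_known=n_known,
        n_negative_excluded=n_negative,
        curves=curves,
    )
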