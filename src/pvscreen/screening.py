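"""PT-level and SOC-level signal screens.

A screen builds every PT's 2x2 table for one exposure, computes the five
disproportionality statistics, applies the per-method thresholds, and
declares a PT a *positive signal* when the combined rule (default
``ror & prr``) holds.  Results are ranked by ROR, mirroring how published
signal tables are presented, and can be annotated with label-listedness
(whether the PT already appears in the product's prescribing information).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .contingency import OVERALL, Stratum, pt_count_frame
from .errors import ConfigError, MappingError
from .model import MedDRAHierarchy, ReportStore
from .rules import parse_rule
from .stats import (
    BCPNNPriors,
    METHODS,
    ThresholdConfig,
    bcpnn_arrays,
    ebgm_arrays,
    flags_arrays,
    prr_arrays,
    ror_arrays,
)


class LabelList:
    """PTs documented in the product label (prescribing information)."""

    def __init__(self, pts: Iterable[str]):
        self.pts = frozenset(p.strip() for p in pts if p and p.strip())
        if not self.pts:
            raise ConfigError("label list is empty")

    def __contains__(self, pt: str) -> bool:
        return pt in self.pts

    @classmethod
    def from_file(cls, path) -> "LabelList":
        with open(path, encoding="utf-8") as fh:
            return cls(line.strip() for line in fh)


@dataclass
class ScreenResult:
    """Ranked PT-level signal table plus screen metadata.

    ``table`` columns: soc, pt, a, b, c, d, ror, ror_lo, ror_hi, prr,
    prr_lo, prr_hi, chi2, ic, e_ic, v_ic, ic025, ebgm, ebgm05, ebgm95,
    flag_<method> for the five methods, positive, label_listed.
    Rows are sorted by ror descending (ties: a descending, pt ascending).
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def positive(self) -> pd.DataFrame:
        if self.table.empty:
            return self.table
        return self.table[self.table["positive"].astype(bool)]

    @property
    def n_positive(self) -> int:
        return int(self.table["positive"].sum())

    @property
    def n_positive_socs(self) -> int:
        return int(self.positive["soc"].nunique())

    @property
    def degenerate(self) -> bool:
        return bool(self.metadata.get("degenerate", False))

    def to_tsv(self, path) -> None:
        """Serialize with 2-decimal half-up presentation rounding.

        Full precision is kept internally; rounding happens only here.
        """
        fmt = self.formatted()
        fmt.to_csv(path, sep="\t", index=False)

    def formatted(self) -> pd.DataFrame:
        def r2(x) -> str:
            if x is None or (isinstance(x, float) and not np.isfinite(x)):
                return "NA"
            return str(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))

        t = self.table
        out = pd.DataFrame(
            {
                "soc": t["soc"],
                "pt": t["pt"],
                "case_reports": t["a"],
                "ror_ci": [f"{r2(v)}({r2(lo)}, {r2(hi)})" for v, lo, hi in zip(t["ror"], t["ror_lo"], t["ror_hi"])],
                "prr_ci": [f"{r2(v)}({r2(lo)}, {r2(hi)})" for v, lo, hi in zip(t["prr"], t["prr_lo"], t["prr_hi"])],
                "chi_square": [r2(v) for v in t["chi2"]],
                "ic_ic025": [f"{r2(v)}({r2(lo)})" for v, lo in zip(t["ic"], t["ic025"])],
                "ebgm_ebgm05": [f"{r2(v)}({r2(lo)})" for v, lo in zip(t["ebgm"], t["ebgm05"])],
                "flags": [
                    "+".join(m for m in METHODS if row[f"flag_{m}"]) or "-"
                    for row in t.to_dict("records")
                ],
                "positive": t["positive"].astype(int),
            }
        )
        if "label_listed" in t.columns:
            out["label_listed"] = [
                "" if v is None else str(bool(v)).lower() for v in t["label_listed"]
            ]
        return out


def screen_pt(
    store: ReportStore,
    exposed_ids: frozenset[str],
    hierarchy: MedDRAHierarchy,
    thresholds: ThresholdConfig = ThresholdConfig(),
    priors: BCPNNPriors = BCPNNPriors(),
    stratum: Stratum = OVERALL,
    rule: str = "ror & prr",
    unit: str = "record",
    z: float = 1.96,
    exposure_label: str = "",
) -> ScreenResult:
    """Screen every PT of the exposure against the comparator background.

    The store must be deduplicated.  Every PT with a >= thresholds.min_a is
    scored; a PT missing from the hierarchy aborts with a
    :class:`MappingError` listing the offenders.
    """
    counts = pt_count_frame(store, exposed_ids, stratum, unit=unit)
    counts = counts[counts["a"] >= thresholds.min_a].reset_index(drop=True)

    degenerate = counts.empty or (counts["a"] + counts["b"]).max() == 0
    predicate = parse_rule(rule)

    if counts.empty:
        table = pd.DataFrame(
            columns=["soc", "pt", "a", "b", "c", "d", "ror", "ror_lo", "ror_hi",
                     "prr", "prr_lo", "prr_hi", "chi2", "ic", "e_ic", "v_ic",
                     "ic025", "ebgm", "ebgm05", "ebgm95"]
            + [f"flag_{m}" for m in METHODS] + ["positive"]
        ).astype({**{f"flag_{m}": bool for m in METHODS}, "positive": bool})
    else:
        missing = {p for p in counts["pt"] if p not in hierarchy}
        if missing:
            raise MappingError(missing)
        a, b, c, d = (counts[k].to_numpy() for k in "abcd")
        ror, ror_lo, ror_hi = ror_arrays(a, b, c, d, z)
        prr, prr_lo, prr_hi, chi2 = prr_arrays(a, b, c, d, z)
        ic, e_ic, v_ic, ic025 = bcpnn_arrays(a, b, c, d, priors)
        ebgm, ebgm05, ebgm95 = ebgm_arrays(a, b, c, d, z)
        flags = flags_arrays(a, ror_lo, prr, prr_lo, chi2, ic025, ebgm05, thresholds)
        table = pd.DataFrame(
            {
                "soc": hierarchy.socs(counts["pt"]),
                "pt": counts["pt"],
                "a": a, "b": b, "c": c, "d": d,
                "ror": ror, "ror_lo": ror_lo, "ror_hi": ror_hi,
                "prr": prr, "prr_lo": prr_lo, "prr_hi": prr_hi,
                "chi2": chi2,
                "ic": ic, "e_ic": e_ic, "v_ic": v_ic, "ic025": ic025,
                "ebgm": ebgm, "ebgm05": ebgm05, "ebgm95": ebgm95,
            }
        )
        for m in METHODS:
            table[f"flag_{m}"] = flags[m]
        table["positive"] = predicate({m: flags[m] for m in METHODS})
        table = table.sort_values(
            ["ror", "a", "pt"], ascending=[False, False, True], kind="mergesort"
        ).reset_index(drop=True)

    result = ScreenResult(
        table,
        metadata={
            "exposure": exposure_label,
            "stratum": stratum.label,
            "unit": unit,
            "rule": rule,
            "min_a": thresholds.min_a,
            "n_pts_tested": int(len(counts)),
            "n_positive": int(table["positive"].sum()) if len(table) else 0,
            "n_positive_socs": int(table.loc[table["positive"], "soc"].nunique()) if len(table) else 0,
            "degenerate": bool(degenerate),
        },
    )
    return result


def concordance(result: ScreenResult) -> dict:
    """Counts of PTs flagged by every subset of the five methods.

    Returns ``{"at_least": {...}, "exactly": {...}}`` keyed by the sorted
    '+'-joined method subset (e.g. ``"prr+ror"``); the empty subset under
    "exactly" counts rows no method flagged.
    """
    t = result.table
    flag_cols = {m: t[f"flag_{m}"].to_numpy(dtype=bool) if len(t) else np.array([], bool) for m in METHODS}
    at_least: dict[str, int] = {}
    exactly: dict[str, int] = {}
    n = len(t)
    profile = [frozenset(m for m in METHODS if flag_cols[m][i]) for i in range(n)]
    for k in range(0, len(METHODS) + 1):
        for subset in combinations(METHODS, k):
            key = "+".join(sorted(subset))
            sub = frozenset(subset)
            at_least[key] = sum(1 for p in profile if sub <= p)
            exactly[key] = sum(1 for p in profile if p == sub)
    return {"at_least": at_least, "exactly": exactly}


def flag_unlisted(result: ScreenResult, label: LabelList) -> ScreenResult:
    """Annotate positive signals with label-listedness.

    Adds a ``label_listed`` column (True/False for positive rows, None for
    non-signals) and per-SOC counts of unlisted signals in the metadata.
    """
    t = result.table.copy()
    listed: list[Optional[bool]] = []
    for row in t.itertuples():
        listed.append(bool(row.pt in label) if row.positive else None)
    t["label_listed"] = listed
    unlisted = t[(t["positive"]) & (t["label_listed"] == False)]  # noqa: E712
    meta = dict(result.metadata)
    meta["n_unlisted"] = int(len(unlisted))
    meta["unlisted_per_soc"] = unlisted.groupby("soc")["pt"].count().to_dict()
    return ScreenResult(t, meta)


def soc_rollup(
    store: ReportStore,
    exposed_ids: frozenset[str],
    hierarchy: MedDRAHierarchy,
    stratum: Stratum = OVERALL,
) -> pd.DataFrame:
    """Per-SOC event-record counts and proportions for the exposure.

    Proportions are of the exposure's total event records and sum to 1.
    """
    counts = pt_count_frame(store, exposed_ids, stratum)
    if counts.empty or counts["a"].sum() == 0:
        return pd.DataFrame(columns=["soc", "records", "proportion"])
    counts = counts[counts["a"] > 0]
    missing = {p for p in counts["pt"] if p not in hierarchy}
    if missing:
        raise MappingError(missing)
    counts = counts.assign(soc=hierarchy.socs(counts["pt"]))
    per_soc = counts.groupby("soc")["a"].sum().sort_values(ascending=False)
    total = per_soc.sum()
    return pd.DataFrame(
        {"soc": per_soc.index, "records": per_soc.to_numpy(), "proportion": per_soc.to_numpy() / total}
    ).reset_index(drop=True)
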