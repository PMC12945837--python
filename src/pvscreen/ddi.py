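"""Co-administration (drug-drug interaction) screens.

The composite-exposure approach: reports listing both the base drug and a
partner form the exposure; all remaining reports (including base-alone)
are the comparator.  The same 2x2 machinery as the single-drug screen
applies.  Each combination signal is cross-checked against the base-alone
screen so combination-specific signals stand out from signals the base
drug carries by itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .contingency import OVERALL, Stratum
from .errors import ConfigError
from .model import (
    DRUG_ROLES,
    MedDRAHierarchy,
    ReportStore,
    SynonymTable,
    exposed_report_ids,
    normalize_drug_name,
)
from .screening import ScreenResult, screen_pt
from .stats import BCPNNPriors, ThresholdConfig


@dataclass(frozen=True, slots=True)
class CombinationExposure:
    """A base drug plus one co-administered partner."""

    base_drug: str
    partner_drug: str

    def __post_init__(self):
        if normalize_drug_name(self.base_drug) == normalize_drug_name(self.partner_drug):
            raise ConfigError("base and partner drug must differ")

    def label(self) -> str:
        return f"{normalize_drug_name(self.base_drug)} + {normalize_drug_name(self.partner_drug)}"


def top_partners(
    store: ReportStore,
    base_drug: str,
    k: int = 8,
    roles=DRUG_ROLES,
    synonyms: SynonymTable | None = None,
) -> pd.DataFrame:
    """The k drugs most frequently co-reported with the base drug.

    Ranked by number of reports containing both, ties broken
    alphabetically.  Returns columns (partner, reports).
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    syn = synonyms or SynonymTable()
    base = syn.resolve(base_drug)
    roles = frozenset(roles)
    counts: dict[str, int] = {}
    for r in store:
        names = {syn.resolve(d.drug_name) for d in r.drugs if d.role in roles}
        if base not in names:
            continue
        for name in names - {base}:
            counts[name] = counts.get(name, 0) + r.weight
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(ranked, columns=["partner", "reports"])


def combination_screen(
    store: ReportStore,
    combo: CombinationExposure,
    hierarchy: MedDRAHierarchy,
    thresholds: ThresholdConfig = ThresholdConfig(),
    priors: BCPNNPriors = BCPNNPriors(),
    stratum: Stratum = OVERALL,
    rule: str = "ror & prr",
    unit: str = "record",
    roles=DRUG_ROLES,
    synonyms: SynonymTable | None = None,
) -> ScreenResult:
    """Screen the base+partner combination against all other reports.

    The result's table gains a ``base_alone_positive`` column: whether the
    base-drug screen (same thresholds and rule) also flags the PT, so a
    True/False split marks combination-specific signals.
    """
    combo_ids = exposed_report_ids(
        store, [combo.base_drug, combo.partner_drug], roles, synonyms
    )
    if not combo_ids:
        return ScreenResult(
            pd.DataFrame(), metadata={"exposure": combo.label(), "degenerate": True, "n_positive": 0},
        )
    result = screen_pt(
        store, combo_ids, hierarchy, thresholds, priors,
        stratum=stratum, rule=rule, unit=unit, exposure_label=combo.label(),
    )
    base_ids = exposed_report_ids(store, [combo.base_drug], roles, synonyms)
    base_result = screen_pt(
        store, base_ids, hierarchy, thresholds, priors,
        stratum=stratum, rule=rule, unit=unit,
        exposure_label=normalize_drug_name(combo.base_drug),
    )
    base_positive = set(base_result.positive["pt"])
    table = result.table.copy()
    table["base_alone_positive"] = table["pt"].isin(base_positive)
    meta = dict(result.metadata)
    meta["n_combo_reports"] = len(combo_ids)
    meta["combination_specific"] = sorted(
        set(table.loc[table["positive"], "pt"]) - base_positive
    )
    return ScreenResult(table, meta)
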