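"""End-to-end orchestration: read -> dedup -> select -> screen -> strata ->
TTO -> DDI -> artifact files.

Every run writes a manifest with the report counts at each stage of the
selection flow, so the provenance of any screened table is reconstructable
from the output directory alone.  Outputs are deterministic for identical
inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .contingency import Stratum
from .ddi import CombinationExposure, combination_screen, top_partners
from .errors import ConfigError
from .model import (
    DRUG_ROLES,
    MedDRAHierarchy,
    ReportStore,
    SynonymTable,
    deduplicate,
    exposed_report_ids,
    select_drug_reports,
)
from .io import read_reports
from .rules import parse_rule
from .screening import LabelList, concordance, flag_unlisted, screen_pt, soc_rollup
from .stats import BCPNNPriors, ThresholdConfig
from .strata import DEFAULT_STRATA, stratified_screen, tto_summary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    reports_path: str
    pt2soc_path: str
    drug: str
    dialect: str = "flat_csv"
    roles: tuple[str, ...] = DRUG_ROLES
    label_path: Optional[str] = None
    synonyms_path: Optional[str] = None
    rule: str = "ror & prr"
    min_a: int = 3
    unit: str = "record"
    continuity_correction: bool = False
    top_k_partners: int = 8
    out_dir: str = "pvscreen_out"
    seed: int = 0

    def validate(self) -> None:
        for path in (self.reports_path, self.pt2soc_path, self.label_path, self.synonyms_path):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"no such file: {path}")
        if not self.drug:
            raise ConfigError("drug must be non-empty")
        parse_rule(self.rule)  # raises RuleError before any computation
        if self.unit not in {"record", "report"}:
            raise ConfigError("unit must be 'record' or 'report'")
        ThresholdConfig(min_a=self.min_a)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "roles" in data:
            data["roles"] = tuple(data["roles"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest dict.

    Artifacts written to cfg.out_dir:
      screen_overall.tsv, screen_<stratum>.tsv, strata_comparison.tsv,
      soc_rollup.tsv, tto_bins.tsv, tto_curves.tsv, ddi_partners.tsv,
      ddi_<partner>.tsv, concordance.json, run_manifest.json.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = ThresholdConfig(min_a=cfg.min_a)
    priors = BCPNNPriors()
    synonyms = SynonymTable.from_csv(cfg.synonyms_path) if cfg.synonyms_path else SynonymTable()
    hierarchy = MedDRAHierarchy.from_csv(cfg.pt2soc_path)

    stages: dict[str, int] = {}
    store = read_reports(cfg.reports_path, cfg.dialect)
    stages["raw_reports"] = len(store)
    log.info("stage=read reports=%d", len(store))

    store = deduplicate(store)
    stages["deduplicated_reports"] = len(store)
    log.info("stage=dedup reports=%d", len(store))

    target = select_drug_reports(store, cfg.drug, cfg.roles, synonyms)
    stages["target_reports"] = len(target)
    exposed = frozenset(r.report_id for r in target)
    stages["target_event_records"] = int(target.event_frame()["weight"].sum()) if len(target) else 0
    log.info("stage=select drug=%s reports=%d", cfg.drug, len(target))

    overall = screen_pt(
        store, exposed, hierarchy, thresholds, priors,
        rule=cfg.rule, unit=cfg.unit, exposure_label=cfg.drug,
    )
    if cfg.label_path:
        overall = flag_unlisted(overall, LabelList.from_file(cfg.label_path))
    overall.to_tsv(out / "screen_overall.tsv")
    stages["pts_screened"] = overall.metadata["n_pts_tested"]
    stages["positive_signals"] = overall.metadata["n_positive"]
    stages["positive_socs"] = overall.metadata["n_positive_socs"]

    with open(out / "concordance.json", "w", encoding="utf-8") as fh:
        json.dump(concordance(overall), fh, indent=1, sort_keys=True)

    rollup = soc_rollup(store, exposed, hierarchy)
    rollup.to_csv(out / "soc_rollup.tsv", sep="\t", index=False)

    results, comparison = stratified_screen(
        store, exposed, hierarchy, thresholds, priors,
        strata=DEFAULT_STRATA, rule=cfg.rule, unit=cfg.unit, exposure_label=cfg.drug,
    )
    for label, res in results.items():
        safe = label.replace("=", "_").replace(", ", "_").replace(">", "ge").replace("<", "lt")
        res.to_tsv(out / f"screen_{safe}.tsv")
    comparison.to_csv(out / "strata_comparison.tsv", sep="\t", index=False)

    tto = tto_summary(store, cfg.drug, roles=cfg.roles, synonyms=synonyms)
    tto.to_frame().to_csv(out / "tto_bins.tsv", sep="\t", index=False)
    curves = []
    for sex, curve in tto.curves.items():
        c = curve.copy()
        c.insert(0, "sex", sex)
        curves.append(c)
    (pd.concat(curves) if curves else pd.DataFrame(columns=["sex", "days", "cumulative"])).to_csv(
        out / "tto_curves.tsv", sep="\t", index=False
    )
    stages["tto_known"] = tto.n_known
    stages["tto_negative_excluded"] = tto.n_negative_excluded

    partners = top_partners(store, cfg.drug, cfg.top_k_partners, cfg.roles, synonyms)
    partners.to_csv(out / "ddi_partners.tsv", sep="\t", index=False)
    for partner in partners["partner"]:
        combo = CombinationExposure(cfg.drug, partner)
        res = combination_screen(
            store, combo, hierarchy, thresholds, priors,
            rule=cfg.rule, unit=cfg.unit, roles=cfg.roles, synonyms=synonyms,
        )
        if not res.table.empty:
            res.to_tsv(out / f"ddi_{partner.replace(' ', '_')}.tsv")

    manifest = {
        "package_version": __version__,
        "config_digest": cfg.digest(),
        "drug": cfg.drug,
        "rule": cfg.rule,
        "unit": cfg.unit,
        "min_a": cfg.min_a,
        "seed": cfg.seed,
        "stages": stages,
        "tto_median_days": tto.median_days,
        "tto_unknown_fraction": tto.unknown_fraction,
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
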