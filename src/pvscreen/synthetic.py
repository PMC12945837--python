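"""Synthetic spontaneous-report databases with known ground truth.

The generator emulates the structure of a public SRS extract: a large
background of (drug, PT) reports from many comparator drugs, a target drug
with a few hundred to a few thousand reports, and named reporting-rate
signals injected multiplicatively — a PT with relative reporting ratio RR
is drawn by target-drug reports with probability proportional to
``background_probability * RR`` (renormalized), so RR is what ROR/EBGM
estimate at small a/N.  Demographics, missingness, onset-time models,
exact-duplicate reports and co-administered partner drugs are all
parameterized, and a manifest records the realized contingency cells so
every pipeline stage can be checked against ground truth.

All randomness flows from one ``numpy.random.default_rng`` seeded from the
config: the same config yields a byte-identical database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .contingency import age_bin, pt_count_frame
from .errors import ConfigError
from .model import (
    CaseReport,
    DrugEntry,
    MedDRAHierarchy,
    ReactionEntry,
    ReportStore,
    deduplicate,
)

_EPOCH = date(2023, 1, 1)

DEFAULT_SOCS = (
    "Injury, poisoning and procedural complications",
    "General disorders and administration site conditions",
    "Infections and infestations",
    "Nervous system disorders",
    "Musculoskeletal and connective tissue disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Gastrointestinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Psychiatric disorders",
    "Cardiac disorders",
    "Vascular disorders",
    "Renal and urinary disorders",
)

DEFAULT_PARTNERS = {
    "umbralisib": 0.20,
    "clemastine": 0.15,
    "armodafinil": 0.12,
    "atorvastatin": 0.10,
    "ocrelizumab": 0.08,
    "paracetamol": 0.07,
    "prednisone": 0.06,
    "sertraline": 0.05,
}


def default_pt_catalog(n_pts: int = 60, socs: Sequence[str] = DEFAULT_SOCS):
    """A deterministic Zipf-weighted PT catalog spread over the SOCs."""
    weights = 1.0 / np.arange(1, n_pts + 1)
    probs = weights / weights.sum()
    return [
        (f"pt_{i:03d}", socs[i % len(socs)], float(probs[i]))
        for i in range(n_pts)
    ]


@dataclass(frozen=True, slots=True)
class InjectedSignal:
    """One ground-truth signal: a PT reported RR-fold more often by the
    target drug, optionally only within a demographic stratum or only in
    reports co-administered with a partner drug."""

    pt: str
    rr: float
    sex: Optional[str] = None
    age: Optional[str] = None
    partner: Optional[str] = None

    def __post_init__(self):
        if self.rr <= 0:
            raise ConfigError("relative reporting ratio must be > 0")


@dataclass
class SyntheticConfig:
    """Full parameterization of the simulated reporting database.

    Demographic and missingness defaults mirror a real anti-CD20 therapy
    cohort in a spontaneous reporting system: a strongly female-skewed sex
    mix (female:male about 3:1), about half of reports missing age, 42%
    missing onset timing, 18% serious, reports concentrated in the
    Americas, and a short median onset time (5 days).
    """

    seed: int = 0
    n_background_records: int = 200_000
    n_target_reports: int = 1235
    extra_reactions_mean: float = 0.8  # reactions per report = 1 + Poisson
    pt_catalog: list = field(default_factory=default_pt_catalog)
    injected_signals: list = field(default_factory=list)
    target_drug: str = "ublituximab"
    n_background_drugs: int = 50
    sex_female_fraction: float = 0.751
    unknown_sex_fraction: float = 0.05
    missing_age_fraction: float = 0.497
    age_bin_weights: dict = field(
        default_factory=lambda: {"<18": 0.03, "18-44": 0.35, "45-64": 0.40, ">=65": 0.22}
    )
    region_mix: dict = field(
        default_factory=lambda: {
            "americas": 0.80, "europe": 0.12, "asia": 0.02,
            "oceania": 0.01, "africa": 0.005, "unknown": 0.045,
        }
    )
    serious_fraction: float = 0.183
    onset_median_days: int = 5
    onset_median_by_pt: dict = field(default_factory=dict)
    missing_tto_fraction: float = 0.4211
    duplicate_fraction: float = 0.02
    partner_drugs: dict = field(default_factory=lambda: dict(DEFAULT_PARTNERS))

    def validate(self) -> None:
        if not self.pt_catalog:
            raise ConfigError("pt_catalog is empty")
        probs = np.array([p for _, _, p in self.pt_catalog], dtype=float)
        if (probs < 0).any() or probs.sum() > 1 + 1e-9:
            raise ConfigError("catalog probabilities must be >= 0 and sum to <= 1")
        for name in (
            "sex_female_fraction", "unknown_sex_fraction", "missing_age_fraction",
            "serious_fraction", "missing_tto_fraction", "duplicate_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        cat_pts = {pt for pt, _, _ in self.pt_catalog}
        for sig in self.injected_signals:
            if sig.pt not in cat_pts:
                raise ConfigError(f"injected signal PT {sig.pt!r} not in catalog")
            if sig.partner is not None and sig.partner not in self.partner_drugs:
                raise ConfigError(f"signal partner {sig.partner!r} not in partner_drugs")
        if self.n_target_reports < 1 or self.n_background_records < 1:
            raise ConfigError("need at least one target report and background record")

    def hierarchy(self) -> MedDRAHierarchy:
        return MedDRAHierarchy({pt: soc for pt, soc, _ in self.pt_catalog})

    # ---- YAML round trip -------------------------------------------------

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["pt_catalog"] = [list(row) for row in self.pt_catalog]
        data["injected_signals"] = [asdict(s) for s in self.injected_signals]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "pt_catalog" in data:
            data["pt_catalog"] = [tuple(row) for row in data["pt_catalog"]]
        if "injected_signals" in data:
            data["injected_signals"] = [
                InjectedSignal(**s) for s in data["injected_signals"]
            ]
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class GroundTruthManifest:
    """What the generator actually produced, for test oracles."""

    target_drug: str
    n_target_reports: int
    n_background_reports: int
    n_duplicates: int
    duplicate_pairs: list
    pt_truth: pd.DataFrame  # pt, soc, true_rr, restriction, expected_a, a, b, c, d
    per_stratum: dict  # stratum label -> {pt: (a, b, c, d)} for injected PTs

    def realized_cells(self, pt: str) -> tuple[int, int, int, int]:
        row = self.pt_truth[self.pt_truth["pt"] == pt]
        if row.empty:
            raise KeyError(pt)
        r = row.iloc[0]
        return int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"])

    def to_json(self, path) -> None:
        data = {
            "target_drug": self.target_drug,
            "n_target_reports": self.n_target_reports,
            "n_background_reports": self.n_background_reports,
            "n_duplicates": self.n_duplicates,
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "pt_truth": self.pt_truth.to_dict("records"),
            "per_stratum": {
                k: {pt: list(cells) for pt, cells in v.items()}
                for k, v in self.per_stratum.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1)


# ---- internals -----------------------------------------------------------


def _sample_sex(rng, cfg, n):
    u = rng.random(n)
    sex = np.where(u < cfg.unknown_sex_fraction, "unknown", "female")
    known = ~(u < cfg.unknown_sex_fraction)
    v = rng.random(n)
    male = known & (v >= cfg.sex_female_fraction)
    sex = np.where(male, "male", sex)
    return sex


_AGE_RANGES = {"<18": (2.0, 18.0), "18-44": (18.0, 45.0), "45-64": (45.0, 65.0), ">=65": (65.0, 90.0)}


def _sample_age(rng, cfg, n):
    bins = list(cfg.age_bin_weights)
    w = np.array([cfg.age_bin_weights[b] for b in bins], dtype=float)
    w = w / w.sum()
    idx = rng.choice(len(bins), size=n, p=w)
    lo = np.array([_AGE_RANGES[bins[i]][0] for i in idx])
    hi = np.array([_AGE_RANGES[bins[i]][1] for i in idx])
    ages = lo + rng.random(n) * (hi - lo)
    missing = rng.random(n) < cfg.missing_age_fraction
    ages[missing] = np.nan
    return np.round(ages, 1)


def _sample_region(rng, cfg, n):
    regions = list(cfg.region_mix)
    w = np.array([cfg.region_mix[r] for r in regions], dtype=float)
    w = w / w.sum()
    return np.array(regions, dtype=object)[rng.choice(len(regions), size=n, p=w)]


def _geometric_onset(rng, median_days: int, n: int) -> np.ndarray:
    """Discrete onset-day model on {0, 1, ...} with the stated median."""
    p = 1.0 - 2.0 ** (-1.0 / (median_days + 1))
    return rng.geometric(p, size=n) - 1


def _split_draws(draws: np.ndarray, counts: np.ndarray) -> list[np.ndarray]:
    return np.split(draws, np.cumsum(counts)[:-1])


def generate(config: SyntheticConfig) -> tuple[ReportStore, GroundTruthManifest]:
    """Generate a reporting database and its ground-truth manifest.

    The returned store still contains the injected exact duplicates (the
    manifest lists the pairs); run :func:`pvscreen.model.deduplicate`
    before screening, as with any raw extract.  Realized contingency cells
    in the manifest are computed on the deduplicated store.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pts = np.array([pt for pt, _, _ in config.pt_catalog], dtype=object)
    socs = {pt: soc for pt, soc, _ in config.pt_catalog}
    bg_p = np.array([p for _, _, p in config.pt_catalog], dtype=float)
    bg_p = bg_p / bg_p.sum()
    n_pts = len(pts)
    median_by_idx = np.array(
        [config.onset_median_by_pt.get(pt, config.onset_median_days) for pt in pts]
    )

    reports: list[CaseReport] = []

    # --- background reports ---------------------------------------------
    n_bg = max(1, int(round(config.n_background_records / (1 + config.extra_reactions_mean))))
    k_bg = 1 + rng.poisson(config.extra_reactions_mean, n_bg)
    drug_w = 1.0 / np.arange(1, config.n_background_drugs + 1)
    drug_w /= drug_w.sum()
    bg_drug_idx = rng.choice(config.n_background_drugs, size=n_bg, p=drug_w)
    bg_draws = _split_draws(rng.choice(n_pts, size=int(k_bg.sum()), p=bg_p), k_bg)
    bg_sex = _sample_sex(rng, config, n_bg)
    bg_age = _sample_age(rng, config, n_bg)
    bg_region = _sample_region(rng, config, n_bg)
    bg_serious = rng.random(n_bg) < config.serious_fraction
    _emit_reports(
        reports, rng, config, prefix="B",
        drug_names=[f"drug_{i + 1:03d}" for i in bg_drug_idx],
        partner_flags=None, draws=bg_draws, pts=pts,
        sex=bg_sex, age=bg_age, region=bg_region, serious=bg_serious,
        median_by_idx=median_by_idx,
    )
    n_background_reports = len(reports)

    # --- target-drug reports ----------------------------------------------
    n_t = config.n_target_reports
    k_t = 1 + rng.poisson(config.extra_reactions_mean, n_t)
    t_sex = _sample_sex(rng, config, n_t)
    t_age = _sample_age(rng, config, n_t)
    t_region = _sample_region(rng, config, n_t)
    t_serious = rng.random(n_t) < config.serious_fraction
    partners = list(config.partner_drugs)
    partner_flags = np.zeros((n_t, len(partners)), dtype=bool)
    for j, name in enumerate(partners):
        partner_flags[:, j] = rng.random(n_t) < config.partner_drugs[name]

    # per-report signal applicability -> grouped multinomial sampling
    signals = list(config.injected_signals)
    applicable = np.ones((n_t, len(signals)), dtype=bool)
    t_age_bins = np.array([age_bin(a) if not np.isnan(a) else None for a in t_age], dtype=object)
    for j, sig in enumerate(signals):
        if sig.sex is not None:
            applicable[:, j] &= t_sex == sig.sex
        if sig.age is not None:
            applicable[:, j] &= t_age_bins == sig.age
        if sig.partner is not None:
            applicable[:, j] &= partner_flags[:, partners.index(sig.partner)]

    t_draws: list[Optional[np.ndarray]] = [None] * n_t
    expected_a = np.zeros(n_pts)
    signatures = [tuple(row) for row in applicable]
    for sig_key in sorted(set(signatures)):
        members = np.array([i for i, s in enumerate(signatures) if s == sig_key])
        p = bg_p.copy()
        for j, on in enumerate(sig_key):
            if on:
                p[pts == signals[j].pt] *= signals[j].rr
        p = p / p.sum()
        counts = k_t[members]
        draws = _split_draws(rng.choice(n_pts, size=int(counts.sum()), p=p), counts)
        for i, d in zip(members, draws):
            t_draws[i] = d
        expected_a += len(members) * (1 + config.extra_reactions_mean) * p

    _emit_reports(
        reports, rng, config, prefix="T",
        drug_names=[config.target_drug] * n_t,
        partner_flags=(partner_flags, partners), draws=t_draws, pts=pts,
        sex=t_sex, age=t_age, region=t_region, serious=t_serious,
        median_by_idx=median_by_idx,
    )

    # --- exact duplicates --------------------------------------------------
    n_dup = int(round(config.duplicate_fraction * len(reports)))
    duplicate_pairs = []
    if n_dup:
        dup_idx = rng.choice(len(reports), size=n_dup, replace=False)
        for j, i in enumerate(sorted(dup_idx)):
            orig = reports[i]
            dup = replace(orig, report_id=f"Z{j:06d}")
            duplicate_pairs.append((orig.report_id, dup.report_id))
            reports.append(dup)

    store = ReportStore(reports, provenance=f"synthetic(seed={config.seed})")

    # --- manifest ----------------------------------------------------------
    deduped = deduplicate(store)
    target_ids = frozenset(
        r.report_id for r in deduped if r.report_id.startswith("T")
    )
    counts = pt_count_frame(deduped, target_ids)
    truth_rows = []
    sig_by_pt = {s.pt: s for s in signals}
    counts_idx = counts.set_index("pt")
    for i, pt in enumerate(pts):
        sig = sig_by_pt.get(pt)
        if pt in counts_idx.index:
            row = counts_idx.loc[pt]
            cells = (int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
        else:
            cells = (0, 0, 0, 0)
        restriction = ""
        if sig is not None:
            parts = [f"{k}={v}" for k, v in
                     (("sex", sig.sex), ("age", sig.age), ("partner", sig.partner)) if v]
            restriction = ", ".join(parts)
        truth_rows.append(
            {
                "pt": pt, "soc": socs[pt],
                "true_rr": sig.rr if sig is not None else 1.0,
                "restriction": restriction,
                "expected_a": float(expected_a[i]),
                "a": cells[0], "b": cells[1], "c": cells[2], "d": cells[3],
            }
        )
    per_stratum = {}
    from .contingency import Stratum

    for sex in ("male", "female"):
        strat_counts = pt_count_frame(deduped, target_ids, Stratum(sex=sex)).set_index("pt")
        per_stratum[f"sex={sex}"] = {
            s.pt: (
                (int(strat_counts.loc[s.pt, "a"]), int(strat_counts.loc[s.pt, "b"]),
                 int(strat_counts.loc[s.pt, "c"]), int(strat_counts.loc[s.pt, "d"]))
                if s.pt in strat_counts.index else (0, 0, 0, 0)
            )
            for s in signals
        }

    manifest = GroundTruthManifest(
        target_drug=config.target_drug,
        n_target_reports=len(target_ids),
        n_background_reports=n_background_reports,
        n_duplicates=n_dup,
        duplicate_pairs=duplicate_pairs,
        pt_truth=pd.DataFrame(truth_rows),
        per_stratum=per_stratum,
    )
    return store, manifest


def _emit_reports(
    reports, rng, config, prefix, drug_names, partner_flags, draws, pts,
    sex, age, region, serious, median_by_idx,
):
    """Materialize CaseReport objects for one block of simulated reports."""
    n = len(drug_names)
    start_offsets = rng.integers(0, 700, size=n)
    missing_tto = rng.random(n) < config.missing_tto_fraction
    receipt_offsets = rng.integers(365, 700, size=n)
    for i in range(n):
        pt_idx = np.unique(draws[i])
        start = None if missing_tto[i] else _EPOCH + timedelta(days=int(start_offsets[i]))
        drugs = [DrugEntry(drug_names[i], "suspect", start)]
        if partner_flags is not None:
            flags, names = partner_flags
            for j, name in enumerate(names):
                if flags[i, j]:
                    drugs.append(DrugEntry(name, "concomitant", start))
        # one AE episode per report: all its reactions share one onset day,
        # drawn from the onset model of its first PT, so the configured
        # median is the report-level time-to-onset median
        onset = None
        if start is not None:
            onset_days = int(_geometric_onset(rng, int(median_by_idx[pt_idx[0]]), 1)[0])
            onset = start + timedelta(days=onset_days)
        reactions = [ReactionEntry(str(pts[idx]), onset) for idx in pt_idx]
        reports.append(
            CaseReport(
                report_id=f"{prefix}{i:07d}",
                case_version=1,
                receipt_date=_EPOCH + timedelta(days=int(receipt_offsets[i])),
                sex=str(sex[i]),
                age_years=None if np.isnan(age[i]) else float(age[i]),
                region=str(region[i]),
                serious=bool(serious[i]),
                drugs=tuple(drugs),
                reactions=tuple(reactions),
            )
        )


# ---- replaying published tables -----------------------------------------


def replay_counts(
    a: int, b: int, c: int, d: int,
    pt: str = "target event",
    target_drug: str = "target drug",
    comparator_drug: str = "comparator drug",
    other_pt: str = "other event",
    max_expand: int = 10_000,
) -> ReportStore:
    """A minimal store whose (target drug, pt) contingency table is exactly
    (a, b, c, d).

    Cells up to ``max_expand`` become individual unit-weight reports;
    larger cells become one aggregated pseudo-report carrying the count as
    an integer weight, so a published table with d of tens of millions
    replays in four rows.  Every counting operation honors weights.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0:
            raise ConfigError(f"cell {name} must be >= 0")
    reports: list[CaseReport] = []

    def emit(cell: str, count: int, drug: str, event: str) -> None:
        if count == 0:
            return
        def make(rid, weight):
            return CaseReport(
                report_id=rid,
                drugs=(DrugEntry(drug, "suspect"),),
                reactions=(ReactionEntry(event),),
                weight=weight,
            )
        if count <= max_expand:
            reports.extend(make(f"{cell}{i:08d}", 1) for i in range(count))
        else:
            reports.append(make(f"{cell}00000000", count))

    emit("A", a, target_drug, pt)
    emit("B", b, target_drug, other_pt)
    emit("C", c, comparator_drug, pt)
    emit("D", d, comparator_drug, other_pt)
    return ReportStore(reports, provenance=f"replay({a},{b},{c},{d})")
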