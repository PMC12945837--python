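"""Co-administration (DDI) screening with a combination-specific signal.

One PT is enriched only in reports where the target drug is taken with a
specific partner.  The combination screen flags it and marks it as
combination-specific (the base drug alone does not carry the signal).
"""

from pvscreen import CombinationExposure, combination_screen, deduplicate, top_partners
from pvscreen.synthetic import InjectedSignal, SyntheticConfig, generate

catalog = [(f"pt_{i:03d}", f"soc_{i % 4}", 1.0 / 30) for i in range(30)]
cfg = SyntheticConfig(
    seed=52,
    n_background_records=40_000,
    n_target_reports=2000,
    pt_catalog=catalog,
    duplicate_fraction=0.0,
    partner_drugs={"partnerin": 0.012, "secondin": 0.10},
    injected_signals=[InjectedSignal("pt_011", 40.0, partner="partnerin")],
)
store = deduplicate(generate(cfg)[0])

partners = top_partners(store, cfg.target_drug, k=5)
print("most frequent co-medications:")
print(partners.to_string(index=False))

res = combination_screen(
    store, CombinationExposure(cfg.target_drug, "partnerin"), cfg.hierarchy()
)
print(f"\ncombination reports: {res.metadata['n_combo_reports']}")
cols = ["pt", "a", "ror", "ror_lo", "positive", "base_alone_positive"]
print(res.table[res.table["positive"]][cols].to_string(index=False, float_format="%.2f"))
print(f"combination-specific signals: {res.metadata['combination_specific']}")
print(
    "\npt_011 is flagged for the drug+partnerin combination but not for the\n"
    "drug alone: the enrichment lives entirely in the co-administered\n"
    "reports, the pattern a true interaction signal would show."
)
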