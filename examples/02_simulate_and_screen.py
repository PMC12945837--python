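"""Simulate a reporting database with known signals and screen it.

Two relative-reporting-ratio signals are injected (RR 10 and RR 3); the
screen should flag them and little else, and the five-method concordance
should show the strong signal caught by every method.
"""

from pvscreen import concordance, deduplicate, exposed_report_ids, screen_pt
from pvscreen.synthetic import InjectedSignal, SyntheticConfig, generate

catalog = [(f"pt_{i:03d}", f"soc_{i % 6}", 1.0 / 50) for i in range(50)]
cfg = SyntheticConfig(
    seed=7,
    n_background_records=60_000,
    n_target_reports=1235,
    pt_catalog=catalog,
    injected_signals=[InjectedSignal("pt_008", 10.0), InjectedSignal("pt_021", 3.0)],
)
store, manifest = generate(cfg)
print(f"simulated {len(store)} reports ({manifest.n_duplicates} exact duplicates)")

store = deduplicate(store)
exposed = exposed_report_ids(store, [cfg.target_drug])
result = screen_pt(store, exposed, cfg.hierarchy(), exposure_label=cfg.target_drug)

print(
    f"screened {result.metadata['n_pts_tested']} PTs -> "
    f"{result.metadata['n_positive']} positive signals "
    f"in {result.metadata['n_positive_socs']} SOCs (rule: ror & prr)"
)
cols = ["pt", "a", "ror", "ror_lo", "prr", "chi2", "ic025", "ebgm05", "positive"]
print(result.table.head(5)[cols].to_string(index=False, float_format="%.2f"))

c = concordance(result)
all_five = "+".join(sorted(("ror", "prr", "mhra", "bcpnn", "ebgm")))
print(f"\nPTs flagged by all five methods: {c['at_least'][all_five]}")
print(
    "\nThe injected RR=10 PT tops the ranking with every lower bound above\n"
    "its threshold; the RR=3 PT is flagged with weaker bounds; null PTs\n"
    "cluster near ROR 1 and stay unflagged."
)
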