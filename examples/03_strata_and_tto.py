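"""Sex-stratified screening and time-to-onset summaries.

A signal injected only into male reports should flag in the male stratum
and not the female one; the time-to-onset summary should recover the
generator's 5-day median and ~42% missing-timing fraction.
"""

from pvscreen import Stratum, deduplicate, exposed_report_ids, stratified_screen, tto_summary
from pvscreen.synthetic import InjectedSignal, SyntheticConfig, generate

catalog = [(f"pt_{i:03d}", f"soc_{i % 5}", 1.0 / 40) for i in range(40)]
cfg = SyntheticConfig(
    seed=11,
    n_background_records=40_000,
    n_target_reports=1000,
    pt_catalog=catalog,
    sex_female_fraction=0.5,
    injected_signals=[InjectedSignal("pt_003", 12.0, sex="male")],
)
store = deduplicate(generate(cfg)[0])
exposed = exposed_report_ids(store, [cfg.target_drug])

results, comparison = stratified_screen(
    store, exposed, cfg.hierarchy(),
    strata=(Stratum(sex="male"), Stratum(sex="female")),
)
for label, res in results.items():
    print(f"{label}: {res.metadata['n_positive']} positive signals "
          f"-> {sorted(res.positive['pt'])}")
print("\ncross-stratum comparison (positive per stratum):")
print(comparison.to_string(index=False))

tto = tto_summary(store, cfg.target_drug)
print(f"\nmedian time to onset: {tto.median_days:g} days "
      f"(unknown timing: {tto.unknown_fraction:.1%}, "
      f"{tto.n_negative_excluded} implausible negatives excluded)")
print(tto.to_frame().to_string(index=False, float_format="%.3f"))
print(
    "\nThe male-only signal appears in the male stratum only, and the\n"
    "0-30 day bin dominates the onset distribution, as configured."
)
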