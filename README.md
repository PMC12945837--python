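# pvscreen

Disproportionality-based signal detection for spontaneous adverse-event
reporting databases (FAERS-style extracts and similar), built as an
importable Python library with a thin `pvscreen` command-line layer.

## The problem

Spontaneous reporting systems collect case reports — a patient, one or
more drugs, one or more adverse reactions coded as MedDRA preferred terms
(PTs).  With no denominator of exposed patients, drug safety signals are
found by *disproportionality*: does drug X's share of reports mentioning
event Y exceed the background share over all other drugs?  Each
(drug, event) pair yields a 2×2 table of event records

|              | target event | other events |
|--------------|:---:|:---:|
| target drug  | a | b |
| other drugs  | c | d |

over which `pvscreen` computes five classical statistics with their
signal thresholds:

- **ROR** = ad/bc, lognormal 95 % CI with SE(ln ROR) = √(1/a+1/b+1/c+1/d);
  signal when a ≥ 3 and the CI lower limit > 1.
- **PRR** = [a/(a+b)] / [c/(c+d)], lognormal CI with
  SE(ln PRR) = √(1/a − 1/(a+b) + 1/c − 1/(c+d)); same threshold.
- **MHRA criterion**: PRR ≥ 2 ∧ χ² ≥ 4 ∧ a ≥ 3, with the uncorrected
  Pearson χ² = (ad−bc)²·N / [(a+b)(a+c)(c+d)(b+d)].
- **BCPNN information component** IC = log₂[aN/((a+b)(a+c))] with
  Dirichlet-posterior moments E(IC), V(IC); signal when
  E(IC) − 2√V(IC) > 0.
- **EBGM** = aN/((a+b)(a+c)) (the same relative reporting ratio on the
  natural scale) with a lognormal interval; signal when EBGM05 > 2.

Around this core the package provides the full analysis pipeline: flat-CSV
and FAERS-ASCII readers, FAERS-style deduplication (latest case version,
then exact-content collapse), PT→SOC rollups, sex/age-stratified screens,
time-to-onset summaries, co-administration (drug–drug interaction)
screens, multi-method concordance, label-listedness flagging — and a
synthetic report generator with injected ground-truth signals so every
stage is testable without database downloads.

## Worked example

A published signal-table row can be rebuilt from its own printed numbers.
The strongest row of the motivating analysis (infusion-related reaction,
581 of 2,245 event records, ROR 354.61, χ² 150,249) determines its full
2×2 table; `examples/01_replay_published_row.py` reconstructs it and
recomputes everything:

```
reconstructed table: a=581 b=1664 c=54514 d=55364884
ROR    354.61 (95% CI 322.53, 389.88)
PRR    263.10 (95% CI 245.18, 282.32)   chi2 150248
IC       8.02 (IC-2SD 7.36)
EBGM   260.33 (EBGM05 236.78)
flags: {'ror': True, 'prr': True, 'mhra': True, 'bcpnn': True, 'ebgm': True}
```

The event is reported ~260–350× more often with the drug than the
database background and every method's lower bound clears its threshold.
`examples/02_simulate_and_screen.py` runs the other direction — simulate
a database with known injected signals, then screen:

```
screened 50 PTs -> 2 positive signals in 2 SOCs (rule: ror & prr)
    pt   a  ror  ror_lo  prr    chi2  ic025  ebgm05  positive
pt_008 352 9.97    8.77 8.48 1826.66   2.55    5.93      True
pt_021 118 2.89    2.38 2.78  125.29   1.09    2.16      True
pt_042  49 1.13    0.85 1.13    0.73  -0.25    0.84     False
```

The injected RR = 10 and RR = 3 PTs are flagged; null PTs sit near
ROR 1.  The remaining examples cover stratified screens and time to
onset (`03`) and combination screening (`04`).

Equivalent shell commands:

```bash
pvscreen simulate --seed 7 --out simdb/
pvscreen screen --reports simdb/reports.csv --drug ublituximab \
    --pt2soc simdb/pt2soc.csv --min-a 3 --rule "ror & prr" --out signals.tsv
pvscreen tto --reports simdb/reports.csv --drug ublituximab --out tto.tsv
```

## Layout

- `src/pvscreen/` — the library (`model`, `io`, `contingency`, `stats`,
  `rules`, `screening`, `strata`, `ddi`, `synthetic`, `pipeline`, `cli`)
- `examples/` — narrative scripts, one per capability
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — models, assumptions, parameter choices, limitations
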