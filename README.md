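# pvsignal

Pharmacovigilance signal detection for spontaneous adverse-event reporting
data, built around the analysis of renal adverse effects of PARP inhibitors
(olaparib, niraparib, rucaparib, talazoparib, veliparib, pamiparib,
fluzoparib) in a FAERS-style report database.

Spontaneous reporting systems collect voluntary adverse-event reports as
quarterly "$"-delimited ASCII tables (DEMO, DRUG, REAC, OUTC, RPSR, THER,
INDI).  The same case appears as multiple report versions, drugs are
free-text names with role codes, and events are MedDRA preferred terms.
`pvsignal` provides the full analysis chain for people who work with such
data — pharmacoepidemiologists and biostatisticians asking "is event E
reported disproportionately often with drug D, how soon after starting
therapy, and with what outcomes?":

* **Ingestion & deduplication** — dialect reader/writer, partial-date
  handling, validation, and keep-the-latest-version deduplication
  (max FDA date per case, ties by max primaryid).
* **Case selection** — drug-synonym dictionary + preferred-term query set +
  primary-suspect role filter; descriptive summaries (region, year, sex,
  age, drug, indication, outcome) with explicit denominators.
* **Disproportionality scan** — for each drug's 2×2 table
  (a = drug∧event, b = event only, c = drug only, d = neither):

  | statistic | formula | signal criterion |
  |---|---|---|
  | ROR | (a/b)/(c/d), CI = exp(ln ROR ± 1.96·s) | CI low > 1, N ≥ 2 |
  | PRR | (a/(a+c))/(b/(b+d)), four-cell χ² | PRR ≥ 2, χ² ≥ 4, N ≥ 3 |
  | IC | log₂(aN/((a+c)(a+b))), IC025 = IC·e^(−1.96·s) | IC025 > 0 |
  | EBGM | aN/((a+c)(a+b)), EBGM05 = EBGM·e^(−1.64·s) | EBGM05 > 2, N > 0 |

  with s = √(1/a+1/b+1/c+1/d).  Interval formulas are deliberately
  verbatim to the source formulation (see `docs/methods.md` for the
  canonical alternatives and the consequences, e.g. EBGM here is the
  unshrunk relative reporting ratio, so IC = log₂ EBGM identically).
* **Time to onset & outcomes** — day-precision EVENT_DT − START_DT with
  categorized exclusions, median/IQR by linear interpolation,
  Mann–Whitney / Kruskal–Wallis / χ² (Yates when expected < 5)
  comparisons, hospitalization and fatality rates under explicit
  denominators.
* **Synthetic SRS generator** — full seven-table datasets with a planted
  drug–event odds multiplier θ, duplicate case versions, missing dates and
  log-normal onset times, plus closed-form expected cells, so the whole
  pipeline is testable with known ground truth.

## Worked example

```python
from pvsignal import (DrugSpec, GeneratorConfig, generate, deduplicate,
                      DisproportionalityModel)

cfg = GeneratorConfig(
    n_reports=50_000, seed=17, duplicate_rate=0.05,
    drugs=(DrugSpec("DrugA", "DRUGA", 0.01, 1.0),    # null drug
           DrugSpec("DrugB", "DRUGB", 0.01, 2.0),    # weak signal
           DrugSpec("DrugC", "DRUGC", 0.01, 8.0)))   # strong signal
dataset, truth = generate(cfg)
dataset = deduplicate(dataset)                        # 52,500 -> 50,000
fit = DisproportionalityModel(dataset, cfg.dictionary(), cfg.pt_query_set()).fit()
print(fit.summary())
```

```
Disproportionality scan
  dictionary: synthetic   event set: synthetic_targets
  roles: PS   unit: reports   chi2: four_cell   intervals: verbatim

 drug  N  ROR  ROR_CI95_low  ROR_CI95_high  PRR   chi2    IC  IC025  EBGM  EBGM05  flag_ror  flag_prr  flag_bcpnn  flag_mgps  flag_all
DrugA 10 0.93          0.50           1.75 0.93   0.05 -0.10      -  0.93    0.55     False     False       False      False     False
DrugB 13 1.19          0.68           2.07 1.18   0.37  0.24   0.14  1.18    0.74     False     False        True      False     False
DrugC 64 6.86          5.24           8.98 6.11 263.41  2.54   1.94  5.81    4.64      True      True        True       True      True
```

Reading the rows: N is the number of deduplicated reports carrying the
drug as primary suspect together with a target event.  The null drug
(θ = 1) hovers at ROR ≈ 1 and trips nothing; the planted θ = 8 drug is
flagged by all four algorithms, its ROR estimating θ (the generator's
exclusive-exposure design makes the population odds ratio equal θ).  A
negative IC has no multiplicative lower bound, so IC025 prints "-" and the
criterion evaluates to no signal.

The same run is available from the shell:

```sh
pvsignal run --seed 17 --out out/        # synthetic demo pipeline
pvsignal dedup --in data/ --out deduped/ # or stage by stage
pvsignal signal --in deduped/ --out signal.csv
```

writing `descriptive_summary.csv`, `signal_table.csv`, `onset_summary.csv`,
`outcome_summary.csv`, a funnel manifest and a run log.

## Layout

```
src/pvsignal/
  io.py          SRS dialect reader/writer, validation, deduplication
  dates.py       partial-date parsing with precision flags
  dictionary.py  drug dictionaries, PT query sets, region/indication maps
  selection.py   cohort selection and descriptive summaries
  signals.py     contingency tables, the four statistics, Model/Results
  onset.py       time-to-onset, nonparametric tests, outcome rates
  simulate.py    synthetic SRS generator + simulation studies
  pipeline.py    config-driven end-to-end run with manifest
  cli.py         `pvsignal` subcommands
  data/          bundled dictionary, PT set, region & indication maps
```
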