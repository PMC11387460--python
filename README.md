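# faerspv

Safety-signal detection on FAERS-style spontaneous adverse-event reports.

Spontaneous-reporting databases such as the FDA Adverse Event Reporting
System (FAERS) collect voluntary reports of suspected adverse drug events
(ADEs).  Because there is no denominator of exposed patients, drug safety
screening on such data relies on *disproportionality analysis*: for a drug
*D* and an event *E* (a MedDRA Preferred Term, PT, or System Organ Class,
SOC), reports are cross-classified into a 2×2 table

|              | event *E* | other events |
|--------------|-----------|--------------|
| reports with *D*    | a | b |
| reports without *D* | c | d |

and the drug–event pair is flagged as a **signal** when all of the following
hold:

* a ≥ 3 reports;
* **ROR** = (a·d)/(b·c) has its Wald 95% CI lower bound above 1,
  CI = exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d));
* **PRR** = [a/(a+b)] / [c/(c+d)] > 2 with Pearson χ² > 4;
* the BCPNN information component **IC** — a Bayesian-shrunken
  log₂(observed/expected) — has its 95% lower credible bound above 0.

Differences in signal strength between two drugs are tested with the
**Breslow–Day** χ² test of odds-ratio homogeneity (Tarone-corrected, on the
Mantel–Haenszel common OR) across the two drugs' strata.

The package provides, as composable library functions and a thin CLI:

* `report_model_io` — the `SafetyReport` data model, a reader for quarterly
  '$'-delimited FAERS ASCII tables (DEMO/DRUG/REAC/OUTC/INDI), and a
  lossless JSON-lines interchange format;
* `preprocess` — case deduplication (latest version per case), drug-name
  standardisation through an alias dictionary, report-level exclusion
  patterns, and exposed/background cohort construction;
* `dpa_core` — contingency tables, ROR/PRR/χ²/IC with intervals, the
  combined signal criterion;
* `drug_comparison` — Breslow–Day homogeneity, the two-drug comparison
  table, volcano-plot coordinates (log₂ROR vs √χ²);
* `descriptives` — demographics/outcome/country/route summaries with
  self-consistent percents, yearly trend series, top-K indication and
  concomitant tables, and the `run_pipeline` orchestrator;
* `synthetic_faers` — a generator of FAERS-like databases with planted
  signal strengths, duplicate case versions, brand-alias noise and
  missingness, so the whole stack is testable without licensed data.

MedDRA is licensed and not bundled: analyses supply a two-column PT→SOC
file, and a mock dictionary ships for tests and demos.

## Worked example

The shipped demo scenario (`configs/demo.yaml`) simulates 20,000 reports for
eight drugs with three planted associations — somnolence (λ = 8) and
pericarditis (λ = 6) for cetirizine, sneezing (λ = 10) for loratadine — plus
10% duplicate case versions and 15% brand-alias noise:

```sh
faerspv run --config configs/demo.yaml --outdir demo_out --seed 7
```

or in Python:

```python
import yaml
from faerspv import run_pipeline

cfg = yaml.safe_load(open("configs/demo.yaml"))
art = run_pipeline(cfg, "demo_out", seed=7)
sig = art["signals_cetirizine_PT"]
print(sig[sig.is_signal].round(2))
```

The cetirizine signal table flags exactly the two planted PTs:

```
       event    a  ror  ror_lo  ror_hi  prr    chi2   ic  ic_lo  is_signal
  SOMNOLENCE 3603 6.82    6.34    7.34 4.20 3055.48 0.88   0.82       True
PERICARDITIS 1191 4.59    4.10    5.14 4.06  804.93 0.87   0.76       True
```

Reading: among the 8,013 deduplicated cetirizine reports, 3,603 mention
somnolence; the odds of a somnolence report are 6.8× higher with cetirizine
than without (CI 6.34–7.34), and all four criteria pass.  The head-to-head
table adds the loratadine side and the Breslow–Day p-value:

```
       event  n_a  ror_a  signal_a  n_b  ror_b  signal_b  bd_p
  SOMNOLENCE 3603  6.822      True  452  0.340     False   0.0
PERICARDITIS 1191  4.592      True  157  0.411     False   0.0
    SNEEZING  521  0.362     False 1441  8.596      True   0.0
```

— each planted signal is specific to its drug and the odds ratios differ
significantly between drugs, as constructed.  `demo_out/` also contains
demographics, trend, top-K, volcano-coordinate and provenance files; reruns
with the same seed are byte-identical.

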