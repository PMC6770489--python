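# ironburden

A probabilistic burden-of-disease model for **dietary iron deficiency (ID)**
and **iron-deficiency anemia (IDA)**, built for nutritional epidemiologists
and risk–benefit assessors who want case counts and DALYs that can respond
to *consumption* scenarios — something hemoglobin-survey-based burden
estimates cannot do.

From a national parameter registry (population counts, absorbed-iron intake
distributions, EFSA requirement distributions, hemoglobin status, WHO
severity thresholds, GBD disability weights — a transcription for
metropolitan France, 2007, ships with the package) the pipeline computes,
per gender × age-class × menstrual-status stratum and nationally:

* ID prevalence: `Prev.ID = P(X < R)`, with absorbed intake
  `X ~ LogN(μ, σ)` and requirement `R ~ N(m, s)`;
* IDA prevalence and cases: `Prev.IDA = Prev.ID × Prop.IDA`,
  `NB_s = Pop × Prev.IDA × Alloc_s`, where the mild/moderate/severe
  allocation `Alloc_s` partitions the anemic tail of the stratum's
  hemoglobin distribution at the WHO thresholds;
* annual burden: `DALY = Σ_s NB_s × w_s`, with severity disability weights
  `w_s` (morbidity only — no mortality term).

Parameter **uncertainty** (intake-fit sampling error, disability weights)
and person-to-person **variability** (requirements, hemoglobin) are kept
separate by a second-order Monte Carlo procedure: 1000 outer iterations over
parameter draws, 10,000 inner iterations over requirement draws with the
lognormal intake CDF integrated in closed form. Every output is reported as
a mean with a 95% uncertainty interval. A scenario engine replaces current
red-meat iron in individual survey records with fixed daily doses of cooked
ground beef (2.6 mg iron/100 g, 25% heme absorption) and recomputes the
whole chain per dose, and a synthetic-survey generator makes the
record-based pathway fully testable without survey microdata.

## Worked example

```
$ ironburden run --seed 1 --out results/baseline
total IDA cases per 100,000/year: 1240 (1183-1294)
total DALY per 100,000/year: 15.7 (10.1-21.4)
```

`results/baseline/burden.csv` holds one row per stratum plus a totals row
(all rates per 100,000 per year; prevalences as fractions):

| gender | age class | status | Prev.ID | IDA cases /100k | DALY /100k |
|---|---|---|---|---|---|
| male | 3–6 | — | 0.087 | 32.4 | 0.27 |
| male | 65–74 | — | 0.036 | 56.3 | 0.65 |
| female | 15–17 | premenopausal | 0.438 | 411.4 | 4.10 |
| female | 18–24 | premenopausal | 0.364 | 78.0 | 1.60 |
| female | 25–44 | premenopausal | 0.319 | 368.0 | 6.74 |
| female | 65–74 | postmenopausal | 0.093 | 12.2 | 0.14 |
| **TOTAL** | | | | **1239.5** | **15.7** |

Reading: menstruating women dominate the burden — 44% of girls aged 15–17
consume less absorbed iron than their requirement, and women 25–44
contribute 6.7 of the 15.7 national DALY per 100,000 per year. A
`manifest.json` (config hash, iteration counts, seed, version) accompanies
every output directory; re-running with the same manifest reproduces the
numbers bit for bit.

Scenario pathway on simulated records:

```
$ ironburden simulate --n 2000 --seed 0 --out results/survey.csv
$ ironburden scenario --records results/survey.csv --doses 0,25,50,75,100 \
      --out results/beef
```

`results/beef/scenario.csv` contains the dose–response table; DALY and ID
prevalence decrease monotonically with the beef dose in every stratum, and
even 100 g/day does not eliminate deficiency among menstruating
adolescents. `ironburden check-stability` reruns the pipeline under three
seeds and reports the worst per-stratum DALY deviation (< 1% at default
iteration counts).

## Layout

```
src/ironburden/parameters.py     typed registry + packaged France-2007 JSON
src/ironburden/survey_ingest.py  imputation, stratification, lognormal MLE + bootstrap
src/ironburden/mc2d.py           second-order Monte Carlo engine
src/ironburden/burden.py         IDA conversion, severity allocation, DALYs
src/ironburden/scenario.py       ground-beef substitution scenarios
src/ironburden/synthetic_data.py survey generator for testing/scenarios
src/ironburden/cli.py            run / scenario / simulate / check-stability
docs/methods.md                  model assumptions, numerical choices, limits
```
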