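# uhccost

A decision model for estimating the recurrent cost of delivering a universal
health-care benefit package through district-hospital infrastructure in
India, for health economists and health-systems planners who need a
transparent, fully parameterized costing pipeline.

## The model

For a reference population of *P* = 100,000, the monthly patient load is

```
L = P × m × a
```

where *m* = 0.1 is the monthly morbidity (care-seeking) rate and *a* = 1.2
adjusts for the extra uptake expected once services are free at the point of
use. A fraction *f* = 0.9 of the load is outpatient (OPD); visits split
across ten clinical specialties by proportional morbidity rates estimated
from one year of hospital service records. Inpatient (IPD) admissions per
specialty follow calibrated admissions-per-visit fractions; bed-days are
admissions × average length of stay (ALOS), and beds required =
bed-days / 30 at full occupancy.

Treatment costs are micro-costed: each specialty's caseload is priced
through standard treatment protocols (quantities of drugs, consumables and
diagnostics × rate-contract unit prices) under a **branded** or **generic**
drug-price column. Conditions lacking an inpatient protocol use an IPD:OPD
cost ratio of 10 (range 8–15) per episode. Surgical package rates are scaled
down by 50% to the cost hospitals actually incur. Monthly treatment,
surgical, salary (5.3 million INR) and overhead components annualize to a
premium per household of 4, and per person; national extrapolation
multiplies the per-capita cost (plus 300 INR/person/year of preventive
care) by the 1.2-billion population and converts to USD and %GDP at a
per-capita GDP of USD 1176.

Uncertainty is handled two ways: a one-way (tornado) analysis sweeping each
parameter across its published range, and a probabilistic sensitivity
analysis drawing all parameters independently (uniform on [low, high] by
default) 1000 times and reporting the 2.5th/97.5th percentiles.

## Worked example

```sh
$ uhccost estimate demand | tail -2
monthly_patient_load: 12000
beds_required: 66
```

100,000 people at a morbidity rate of 0.1/month and uptake adjustment 1.2
generate 12,000 patient contacts a month, needing 66 inpatient beds.

```sh
$ uhccost estimate costs --scenario generic | tail -4
  "monthly_surgical_inr": 1441994,
  "monthly_treatment_total_inr": 8330541,
  "annual_per_household_inr": 6852,
  "annual_per_person_inr": 1713
```

With generic drugs, treating that caseload costs 8.33 million INR a month
(11.67 million with branded drugs — 1.4× higher); adding salaries and
overhead, the benefit package costs 6852 INR per household (1713 INR per
person) per year.

```sh
$ uhccost estimate national --scenario generic
{
  "scenario": "generic",
  "annual_curative_inr_billion": 2055,
  "annual_total_inr_billion": 2415,
  "annual_curative_usd_billion": 46.0,
  "annual_total_usd_billion": 54.0,
  "gdp_share_percent": 3.8
}
```

Universalized across 1.2 billion people, curative care costs 2055 billion
INR/year; with preventive care, 2415 billion INR (USD 54 billion), i.e.
3.8% of GDP (4.7% with branded drugs).

Other subcommands: `uhccost estimate scale-curve` (household cost by
hospital bed strength), `uhccost tornado`, `uhccost psa --n 1000 --seed S`,
`uhccost synth` (synthetic service records), and `uhccost run --out DIR`
(full pipeline with a reproducibility manifest).

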