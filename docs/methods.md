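# Methods

## Model structure and assumptions

The package implements a deterministic cohort-style decision model: a
reference population generates a monthly patient load, the load is routed
through outpatient and inpatient pathways, each pathway is costed bottom-up,
and the total is expressed as an annual premium per household and per person
and extrapolated nationally. The model uses deterministic monthly averages
throughout — there is no patient-level queueing, seasonality or occupancy
simulation; a bed is assumed available 30 days a month at 100% occupancy.

Demand chain:

- `monthly_load = population × morbidity_rate × reporting_adjustment`
  (100000 × 0.1 × 1.2 = 12000). The morbidity rate is a monthly
  probability of falling ill *and* seeking care; the adjustment of 1.2
  anticipates extra uptake when services carry no price at the point of use.
- An outpatient fraction of 0.9 routes 10,800 contacts/month to OPD. The
  parameter tables also carry an inpatient-treatment proportion (0.05) and
  correction factor (0.3); their published composition into the OPD/IPD
  split is not arithmetically recoverable, so the model carries a single
  calibrated `opd_fraction` and, in sensitivity analyses only, scales the
  inpatient share multiplicatively:
  `ipd_share = 0.1 × (p/0.05) × (c/0.3)`, clipped to [0, 0.99].
- Specialty OPD shares used for the base-case tables are derived exactly
  from the recorded visit counts (visits / 10799); the coarser published
  share values (which sum to 1.01) are renormalized and used only as
  sensitivity-analysis parameters, because at their printed 1-dp precision
  they cannot regenerate the recorded visit cells. Integer visit allocation
  uses largest-remainder rounding, which preserves the total exactly.
- Admissions per specialty are visits × a calibrated admissions-per-visit
  fraction `(bed_days/ALOS)/visits`; bed-days are admissions × ALOS. Dental
  has 2 recorded bed-days and no ALOS; it is carried as a direct bed-day
  override treated as one pooled monthly admission.
- Beds required = total monthly bed-days / 30, half-up. The recorded
  per-specialty bed-day cells sum to 1,983 (the printed sub-total is 1,984;
  the 1-unit gap is a rounding artifact in the source table); both give 66
  beds. The default beds-per-100,000 used for hospital-scale scenarios is
  the unrounded 1984/30.

## Costing

Episode costs are micro-costed as Σ quantity × unit price over a protocol's
line items, with a branded and a generic price column (generic ≤ branded
for drugs; identical for consumables/diagnostics). The shipped protocol
fixture is **calibrated**: the underlying drug-level protocols are not
published, so each specialty carries one pooled outpatient protocol whose
per-episode cost equals the recorded monthly OPD cost ÷ recorded visits, and
one pooled inpatient protocol at recorded monthly IPD cost ÷ implied
admissions. This preserves every recorded aggregate bit-for-bit while
keeping the costing machinery fully general for user-supplied protocol and
price files. Conditions lacking an inpatient protocol are costed at
`opd_episode_cost × ratio` with ratio 10 (8–15), interpreted per episode,
not per bed-day. Surgical package rates (fixture total 2,883,988 INR/month)
are scaled by 50% exactly once, to 1,441,994 INR/month.

Monthly components beyond treatment:

- **Salaries**: a single scalar, 5.3 million INR/month, from a survey of
  private-hospital salary structures. A configurable staffing-norms
  calculation (ceiling(workload/norm) per cadre) exists for exploring
  headcounts, but the published norms are unavailable, so headcounts are
  not a reproduction surface; the default norms are calibration examples
  (25 consults/specialist/day, 1 ANM per 5,000 population).
- **Overhead**: an explicit residual, calibrated per drug scenario —
  644,459 INR/month (generic) and 1,344,836 INR/month (branded) — because
  the published treatment + salary components alone annualize to ~6543
  INR/household, not the published 6852. A transparent residual was
  preferred to silently inflating another component; the residual differs
  by scenario because the published premium gap between scenarios exceeds
  the treatment-cost gap.

Premiums: `annual_total = 12 × Σ monthly components`;
`per_household = annual_total / (population/household_size)`;
`per_person = per_household / 4`.

## National extrapolation

Per-capita curative cost (+300 INR/person/year preventive) × 1.2 billion
people. Billion-INR figures use floor, matching the printed convention
(1713 × 1.2 = 2055.6 → 2055). The %GDP share converts the curative
per-capita cost to whole USD first (the precision at which the source
figures were evidently computed: divide-then-round yields 6.7 for the
generic upper bound where the published value is 6.8), adds the preventive
cost unrounded, divides by per-capita GDP (USD 1176) and reports 1 dp. The
exchange rate defaults to 1713/38 ≈ 45.079 INR/USD, the value implied by
the published INR/USD pair; no explicit rate is published, and this
unrounded value reproduces every published USD conversion. The
branded-over-generic increase (24%) is computed on the preventive-inclusive
per-capita total, the only definition consistent with the published figure.

Hospital-scale scenarios: a hospital of *B* beds efficiently serves
`B / (1984/30) × 100,000` people; treatment and surgical costs scale with
population (constant per household) while salaries + overhead are amortized
over the catchment's households, giving a per-household cost strictly
decreasing in bed strength. The fixed/variable split behind the published
per-bed-strength costs is unpublished, so only these qualitative properties
are asserted.

## Sensitivity analysis

- **Tornado**: each parameter evaluated at its low and high bound, others
  at base, ranked by swing. Parameters flagged `derived`, `fixed` or
  `range_inconsistent` (the monthly-load row, whose printed upper bound
  41,040 is internally inconsistent) are excluded.
- **PSA**: 1000 draws by default, every sampled parameter drawn
  independently and uniformly on [low, high] — the published ranges are the
  only uncertainty information available; the sampling distribution is
  pluggable (triangular is included). Specialty shares are renormalized
  inside the model after sampling so they always sum to 1. Percentiles use
  linear interpolation; the seed is a required, logged input.
- The outcome model is calibrated once against base values (per-visit and
  per-bed-day unit costs, admission fractions) so that evaluating it at
  base reproduces the base-case premium exactly. The IPD:OPD cost-ratio
  parameter scales inpatient unit costs relative to its base of 10;
  treatment and surgical costs scale with realized load while salaries and
  overhead stay fixed, which is what makes the premium sensitive to
  population size. The %GDP outcome inside the sensitivity model is
  continuous (no whole-USD rounding) to keep tornado/PSA outputs smooth.

The published one-way result cells are **not** reproduction targets: they
imply a baseline inconsistent with the published premium table, so the
machinery is verified against closed-form toy models instead.

## Synthetic data

The generator emulates one year of administrative service records:
specialty ~ categorical(proportional morbidity rates), setting ~
Bernoulli(OPD fraction), and inpatient length of stay ~ 1 + Poisson(ALOS−1)
— positive, integer, mean-matched, chosen because only mean ALOS is
published; real stay distributions are more overdispersed, so recovery
results say nothing about LOS dispersion. Records carry no diagnoses:
protocol selection is modeled at specialty level, not at the disease level
of the original burden analysis. Setting and specialty are drawn
independently, so admissions-per-visit is constant across specialties in
synthetic data, unlike the calibrated real-data fractions (0.002–0.02).
Passing parameter-recovery tests therefore demonstrates estimator
correctness at realistic sample sizes (100,000 encounters ≈ the annual
contact volume of the reference population), not robustness to the
heterogeneity of real administrative data.

## Numerical choices and degenerate inputs

- Half-up rounding for beds, USD and %GDP reporting (Python's banker's
  rounding is avoided where the printed convention is half-up).
- Price/protocol fixtures store full-precision float reprs; forward
  products reproduce the recorded integer cells after rounding to 1 INR.
- Zero population, zero exchange rate, negative quantities, occupancy
  outside (0, 1], episode weights > 1, generic > branded prices, and
  low > high ranges all raise `ValidationError` early.
- Problem sizes: the default PSA uses 1000 draws (matching the study
  design); distributional checks of the percentile machinery use 100,000
  draws of a one-parameter model; parameter recovery uses 100,000 synthetic
  encounters. Each runs in well under a minute.

## Known limitations

- Staffing headcounts, the one-way result cells and the per-bed-strength
  household costs are configurable/qualitative only (inputs unpublished or
  internally inconsistent — see above).
- Overhead is a calibrated residual, not an observed component.
- No capital expenditure, depreciation, inflation adjustment, or correlated
  parameter sampling; no disease-level burden modelling.
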