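# Methods

This note documents the models in `panelcost`, the parameters that matter,
the calibration choices made where the published material is incomplete,
and what the synthetic data can and cannot show.

## Activity-based costing

Each panel × platform combination is described by a cost decomposition
(`PanelCostSpec`): fixed yearly equipment cost, fixed per-run personnel and
material cost, and variable per-sample personnel and material cost. The
packaged decompositions are the published whole-euro values; they are also
reproducible from the packaged activity schedules via
`aggregate_panel_costs`, which prices personnel minutes with per-role rates
(euros per direct productive minute) and sums materials and annualised
equipment.

**Calibrated constants.** Per-role hour rates, and the split of run-level
personnel time into minutes-per-run, are not public; the published schedules
list all time per sample. The packaged schedules therefore book the
sequencing run, run QC and batch review as per-run minutes, and the six
per-minute rates are solved exactly against the four published personnel
aggregates (small/medium × per-run/per-sample). The resulting rates
(€28.7–€120 per hour, secretary < technician < molecular biologist <
bioinformatician < board < pathologist) are economically plausible employer
costs over productive hours, but they are calibration constants, not
measurements. Equipment sums reproduce the published yearly totals exactly
except the medium panel on the high-throughput sequencer, where the
published table is internally inconsistent by €1; the canonical spec keeps
the printed value and the schedule route is tested to ±€1. One medium-panel
QC consumable is set to €118 (the printed schedule says €117) so the
per-sample material total matches the published €136.

**Cost model.** `cost_per_sample` spreads the yearly fixed cost over
`52 × runs_per_week` runs, adds the fixed per-run cost and the variable cost
of `fill × samples + controls` samples, divides by the effective patient
samples and applies the overhead multiplier. Decisions embedded here:

* overhead (default 30%) applies multiplicatively to the full per-sample
  cost; VAT is treated as embedded in material purchase prices;
* control samples (1 for runs of ≤8 booked samples, 2 from 9) incur
  variable cost only, keyed off the *booked* run size;
* the fill fraction applies to booked patient samples (`n_p = fill × s`);
* rounding to whole euros (half away from zero) happens only at reporting.

Under these conventions the base plan (24 samples, 1 run/week, 85% fill)
gives €611 / €962 (small panel, benchtop / high-throughput) and €1,136
(medium, high-throughput) against published €606 / €956 / €1,137 — within
the published tables' own ~0.8% internal drift. The published minimum €465
corresponds to a completely full 48-sample run (we get €466), the maximum
€1,769 to an 85%-filled 4-sample run (€1,765); both fill conventions are
plain plan parameters. Two published values (€3,009 for the medium panel on
the benchtop machine, and the €2,614 sensitivity bound) are not reproducible
from the printed inputs under any convention we found and are deliberately
out of scope.

Strict monotonicity of cost per sample in `samples_per_run` holds whenever
the per-run fixed cost exceeds roughly `7 × fill × variable cost` (the
second control sample enters at nine booked samples); this holds for all
packaged panels, and the property tests assert it there rather than for
arbitrary decompositions.

## Budget impact analysis

The BIA is deterministic. A scenario cell (time frame × indication ×
stratum) carries a test bundle with applicability fractions; fractional
applicability is an expected cost per patient, not patient-level sampling.
Stratum shares (NSCLC 70% peripheral / 30% specialised; melanoma 30% / 70%)
must sum to one per frame and are validated before computation. Populations
are fixed per frame: 4,045 → 4,474 (NSCLC) and 800 → 887 (melanoma), taken
as configured rather than recomputed from the underlying 11%/5-year growth
(whose rounding differs by a few patients).

**Unit-cost calibration.** The published unit-cost overview rounds to whole
euros, but the published population totals imply slightly different working
values. Solving the population cells for the unit costs gives a Sanger
sequencing price of €294.5 and a fragment-analysis price of €294.0 (the
overview prints €295 for both); the remaining entries (€265 HRM, €309 FISH,
€500 multigene panel, €606/€1,137 panels, €1,100 WGS) are used as printed.
With this catalog all six frame costs per patient are exact after rounding
(€537/€864/€754 NSCLC, €480/€616/€952 melanoma) and the population impacts
agree within 0.05%. The rounded-catalog variant ships as
`netherlands_printed`. For NSCLC current/peripheral the model uses two
single-gene tests (€590), which reproduces the €864 frame cost; the
alternative €559 table-cell variant ships as `netherlands_table2`.

The projected WGS price is `USD/genome × genomes/patient × (1 − reduction)
× USD→EUR`: four genomes per patient (tumour in triplicate plus germline),
a 75% price reduction over five years, 0.88 USD→EUR — €1,100 per patient.

## Sensitivity analysis

One-way analysis only: each parameter is evaluated at its low and high
value with everything else at base; the tornado sorts by descending outcome
range (stable under ties). The default range is ±20% relative. For the
future-frame tornado, price perturbations (and the specialised-care share,
with the peripheral share renormalised) apply to the future frame only —
the current frame keeps base prices; this is the only reading that
reproduces the published panel-price swing. The current-situation cost
tornado prices the small panel with the ABC model and adds 0–3 additional
single-gene tests (fragment analysis, Sanger, FISH); published ranges for
its plan parameters are not documented, so the packaged ranges
(samples 4–48, runs 1–5/week, fill 0.5–1.0, tests 0–3) are in-house
plausible values and callers can supply their own.

## Case study and statistics

Per-patient cost is the sum of the unit costs of the tests performed.
Between-period comparisons follow the conventional selection rule:
continuous variables are screened per group with Shapiro–Wilk at α = 0.05
(both groups must pass for the t-test; degenerate zero-variance groups
count as non-normal), otherwise a two-sided Mann–Whitney U; binary category
flags form 2×2 tables tested with Fisher's exact test, two-sided by the
point-probability method (summing all tables no more probable than the
observed one — verified against exhaustive hypergeometric enumeration to
1e-12). Variables constant in both groups are marked degenerate with the
p-value omitted. No multiple-testing correction is applied across
variables. The per-period "cost per test" summary pools the unit costs of
all tests in the period; in the between-period comparison the continuous
unit is the per-patient mean cost per test.

Annualisation assumes the observation window's intake rate is
representative: `yearly = round(patients / months × 12)` (3.5-month window:
100 NSCLC patients → 343/year, 72 melanoma → 247/year). The institutional
budget impact is the change in mean per-patient cost scaled by the yearly
count.

## Synthetic cohorts

The generator emulates the case study's *utilisation and cost structure*
only: per-patient test counts (shifted Poisson truncated to the profile
range), test types (weighted sampling without replacement from the profile
mix), mutation counts (truncated Poisson) and independent Bernoulli
category flags. Both count distributions are mean-calibrated *under
truncation* (the rate is solved so the truncated mean hits the profile
mean), which is what makes large-cohort parameter recovery exact; a raw
clamped Poisson would bias the mean wherever the range binds (e.g. a 0–1
mutation range with mean 0.75). The count family is a modelling choice —
only means and ranges are published.

Packaged profiles encode the four published cohort arms; their test mixes
are tuned so the implied mean cost per patient is close to the published
period means (within ~2%). Because draws are without replacement, realised
test frequencies are flatter than the nominal weights; the mixes were
chosen with that in mind. What passing tests show: the pipeline's
statistics behave correctly on data with the published first-order
structure (location shifts of the published size are detected with high
power; identical profiles reject at ≈5%). What they do not show: anything
about correlations in the real cohort (test count vs mutation count are
independent here, category flags are independent although some real
categories are mutually exclusive), about real test-mix composition, or
about the published within-cohort p-values, which depend on unpublished
patient-level data.

## Numerical and reporting conventions

All composition is on unrounded floats; euro rounding (half away from zero)
is applied only when reporting, matching the ±€1 drift visible in the
published tables. CSV exports use plain integers, no thousands separators.
Exports carry a manifest with package version and seed but nothing
time-dependent, so identical config + seed gives byte-identical artifacts.
Truncated-Poisson calibration uses Brent root-finding on the closed-form
truncated mean (cached per profile). All model computations used in the
tests and the acceptance script run in well under a second; the statistical
simulations (200-replicate power check, 1,000-seed type-I-error check,
n = 10,000 recovery) are sized to keep the full suite around half a minute.

## Known limitations

Treatment costs and downstream consequences of testing are out of scope, as
are repeat testing over disease progression, the RNA part of the medium
panel, turnaround-time modelling, and probabilistic (multi-way) sensitivity
analysis. The unit-cost calibration resolves the published tables'
rounding inconsistencies but cannot recover the true underlying accounting;
where two published figures conflict (€559 vs €590; €2,614; €3,009) the
choice and the unreproduced values are documented above.
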