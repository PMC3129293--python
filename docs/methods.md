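# Methods

`khscm` implements a facility-level step-down costing engine of the kind used
to cost national essential health packages in low-income settings, together
with the surrounding machinery a national costing exercise needs:
annualization of expenditures and assets, unit costs per outpatient visit /
admission / bed-day, per-condition episode costing, aggregation of a
stratified facility sample to a national cost matrix, and fixed/variable
scenario simulation. This note records the model, its parameters, the
numerical conventions, and the deliberate design choices.

## Cost model

Each facility is a ledger of cost items in four input categories — drugs and
other supplies, staffing, other recurrent cost, fixed (annualized capital)
cost — over two fiscal years, plus a cost-centre structure, an asset
register, a payroll and annual service statistics. An item is *direct* if it
is attributable to a single costing unit (an outpatient visit, an admission)
and *indirect* if it is attached to the cost centre where it occurs. Cost
centres are *support* centres (administration, laundry, kitchen) or *final*,
patient-serving centres (outpatient department, wards).

### Annualization

* Two observed fiscal years are averaged with the earlier year uplifted by a
  standard inflation rate (default 5%/year):
  `(c₁·(1+π) + c₂)/2`. Only the two-year average is implemented; the rate is
  exposed but no compounding rule is assumed for longer horizons.
* Capital is charged by straight-line depreciation with class-default
  service lives: general equipment 10 y, medical equipment 8 y, vehicles
  8 y, buildings 30 y, overridable per asset. Buildings may be valued as
  floor area × regional build cost per m². A multiplicative
  `condition_adjustment` on the lifetime stands in for condition-based
  life adjustment (how the original adjustment was done is not specified
  anywhere, so the simplest monotone mechanism was chosen). No salvage
  value and no mid-year convention: the annual charge times the effective
  life returns the initial value exactly.
* Staff time is valued at full remuneration (base + allowances) divided by
  expected direct-service minutes per year; defaults of 220 working days ×
  6 direct hours × 60 min give a 79,200-minute denominator. Missing pay is
  imputed from the equivalent public-sector scale and flagged.
* In-kind supplies (mainly pharmaceuticals) are valued from the ministry
  price list as drugs/supplies items.
* All amounts are kept in Ksh; conversion to EUR uses the fixed study rate
  of 90.66 Ksh/€. Amounts are stored as floats quantized to whole cents at
  ingest; rounding (half away from zero) is applied only at reporting.

### Step-down allocation

Classic one-pass step-down: support centres are closed one at a time; each
closed centre distributes its accumulated cost (own indirect cost plus
anything received from earlier closures) over all not-yet-closed centres in
proportion to an allocation basis; closed centres never receive cost back,
so reciprocal allocation is structurally impossible. Category identity is
preserved through the cascade (an allocated drugs cost stays a drugs cost),
which is what later supports the fixed/variable decomposition.

Conventions, chosen where the method leaves freedom:

* Default closure order: descending accumulated indirect cost, ties broken
  by centre id; an explicit order list can reproduce any published ordering.
* Default basis: *direct-cost share* — each receiver weighted by its own
  pre-allocation indirect cost. It is always computable and scale-free.
  Weights are frozen before the cascade rather than updated as centres
  accumulate cost. A consequence worth knowing: with one shared static
  weight vector the cascade telescopes, and the final split is independent
  of the closure order; order sensitivity (a real feature of step-down in
  practice) appears only when different centres use different bases. Both
  behaviours are covered by tests.
* Output-statistic bases (bed-days, outpatient visits) read the receiving
  centres' output counts; staff-count and floor-area bases require explicit
  weights.

Unit costs divide allocated pools by outputs: final centres measured in
visits form the outpatient pool; centres measured in bed-days or admissions
form the inpatient pool, divided by bed-days and by admissions respectively —
so the admission/bed-day cost ratio is the average length of stay, and the
two ratio columns of the unit-cost report reproduce from the published unit
costs under half-away-from-zero 1-dp rounding. A facility with nonzero cost
against a zero output count is excluded and counted, never silently dropped.

### Episode costing

An episode's cost is `direct + indirect`, exactly. The direct component
prices the treatment recipe (drug quantities by age group, staff minutes by
cadre, lab tests); the indirect component uses only the *indirect share* of
the unit cost — per visit for outpatient episodes, per bed-day × length of
stay for inpatient episodes — so directly priced drugs and staff time are
not double counted. Recipes come in *actual* (observed use, stock-outs
included) and *normative* (expert standard) variants costed against the same
overheads. Episode costing takes an age-group argument defaulting to the
under-5 group.

Demand-side adjustment folds the stratum mean of *outside-facility drug
purchases* from exit interviews into the cost per visit (outpatients) and
per admission (inpatients), as unweighted sample means per stratum ×
patient type. User fees and transport costs are collected but deliberately
not added. An empty interview cell skips the adjustment with a logged
warning.

### Aggregation and shares

Facility category costs are expanded by per-stratum sampling weights
(default 1 — the sample is reported as itself, since no expansion method is
specified) into a stratum × category matrix with exact margins. Trustee
shares are row-group sums over the grand total, in integer percent. The
bundled national summary fixture reproduces: grand total 694,947,102 €,
staffing 37% of total and 52% of recurrent, drugs 22%, FBO/NGO 17%, private
23%. Two documented quirks:

* The printed summary is internally inconsistent at the 1-€ level (its cells
  sum to one euro less than its printed grand total, and one column margin
  is one euro short). The bundled fixture raises a single other-recurrent
  cell by 1 € — which simultaneously reconciles that row's own printed
  total, the column margin and the grand total.
* The nursing-home row printed without a trustee label is carried in the
  denominator but outside every trustee group: that is the convention under
  which the printed 17%/23% shares reproduce (including it in the private
  group gives 24%). The printed 54% public share does not reproduce from
  the summary rows (the public-labelled rows give ≈52% and administration
  ≈7% vs the printed "some 6%"); these discrepancies are reported, not
  forced.

### Scenarios

*Standard occupancy.* Standard bed-days = beds × 365 × 0.85 (default). The
fixed component of the cost per bed-day is rescaled by actual/standard
bed-days; the variable component is unchanged; the cost per admission is the
actual average length of stay × the standard bed-day cost. At actual
occupancy equal to the standard the restatement is the identity; an
under-utilized facility's standard costs are strictly lower.

*Coverage response.* With fixed/variable totals (F, V) from the matrix —
policy `fixed_only` (capital column) or `fixed_plus_staffing` (hiring
treated as sticky) — demand multiplier m costs `F + mV`, a factor
`(F+mV)/(F+V) ≤ m`: coverage growth is subproportional whenever F > 0.
Baseline coverage defaults to 25% of theoretical need. Above a
capacity-utilization threshold (default 1.4 × baseline), discrete capacity
blocks (default size 0.2 utilization units) are added at a configured step
cost, making the curve piecewise; the default step cost is 0 so expansion
is opt-in. The exact fixed/variable classification behind the published
"factor 2.11 at tripled demand" is not recoverable: the bundled summary
gives 2.45 under `fixed_only` and 1.70 under `fixed_plus_staffing`, so the
published factor is treated as a qualitative anchor (subproportional,
below 3) rather than a target.

## Synthetic generator

The generator emulates the survey's inputs, not any published algorithm.
Defaults encode the study conditions:

* Stratum plan: 154 facilities — 85 government (20 dispensaries, 27 health
  centres, 20 district, 7 provincial, 2 tertiary hospitals, 9 administration
  units split 7 district + 2 provincial; the split is not given in print),
  35 FBO/NGO (24 dispensaries/health centres, 10 district hospitals, 1
  nursing home), 34 private (10 dispensaries/health centres, 11 district
  hospitals, 1 tertiary hospital, 12 nursing homes) — plus the central
  ministry as a separate super-overhead record outside the facility count.
* Per-stratum category scales default to the published summary cells (in
  Ksh) divided by the stratum's facility count, so the expected sample
  aggregate matches the published matrix. Because weights default to 1,
  per-facility amounts are national-scale: the sample *is* the nation in
  this synthetic world — adequate for testing arithmetic, shares, ratios
  and directions, not for per-facility realism.
* Monetary draws are mean-one log-normal multipliers times the scale;
  sigma defaults 0.25 (public), 0.5 (FBO/NGO), 0.7 (private), 0.1
  (administration), reproducing the wide private-sector spread.
* Occupancy means: public district 107%, provincial 90%, tertiary 95%;
  FBO/NGO 60%; private 45% — over-capacity public hospitals and
  under-utilized private ones. Bed complements, visit volumes and stay
  lengths are level-typical constants with drawn noise.
* Ledgers are emitted for both fiscal years so the inflation-averaging path
  is exercised end to end; the asset register is constructed so its
  straight-line charge equals the drawn annual fixed cost; the payroll sums
  to the staffing ledger.
* 1369 exit interviews by default, with higher outside-drug means for
  public facilities (stock-outs) than private ones.
* 59 conditions × (actual, normative) recipes; actual drug quantities are
  normative ones times a drawn availability factor ≤ 1, so normative direct
  cost dominates actual condition by condition.
* Per-stratum fixed-cost shares are validated against a configurable band,
  default 5–55%, bracketing the published per-stratum range (9–48%) around
  the 27.6% overall fixed share.

**Calibration.** All random consumption is independent of the scales, so
calibration to a target matrix is a deterministic rescale: generate,
compute per-row per-category ratios target/actual, multiply the stratum
scales, regenerate with the same seed — residuals are at floating-point
level (~10⁻⁹ relative). Two published rows are not generatable under the
default plan: the community row (level-1 community costing is out of model
scope) and the public nursing-home row (absent from the sample plan; adding
one would break the 85/35/34 trustee margins). Calibration therefore takes
an `ignore_rows` list; the full-coverage calibration run extends the plan
with one public nursing home and ignores only the community row, leaving
the calibrated grand total within 0.11% of the published 694,947,102 €.

## Numerical conventions and limitations

* Report rounding is half away from zero (`round_half_away`); Python's
  built-in banker's rounding is never used on reported figures.
* Occupancy above 100% is a legal state (it is observed); only occupancy
  above 150% of capacity is flagged, as an arbitrary sanity bound, and at
  warning severity.
* Fiscal years are opaque labels ordered by ledger metadata, never parsed.
* Step-down conservation (final totals + direct costs = ledger total) holds
  to ~10⁻⁹ relative error and is property-tested against an independent
  brute-force sequential-distribution oracle on small instances.
* The generator does not attempt epidemiologically realistic disease mixes,
  geographic structure, or realistic per-facility cost magnitudes (see the
  sample-as-nation convention above); passing tests demonstrate the
  engine's arithmetic and the published aggregate relationships, not
  field realism.
* Absolute published unit costs and episode costs are not reproducible from
  the bundled aggregates (they require unpublished facility micro-data);
  only their internal ratios and qualitative orderings are asserted.
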