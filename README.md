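# khscm

A step-down costing engine for national health-facility samples, built for
health economists costing an essential health package across a stratified
sample of facilities (dispensaries through tertiary hospitals, across
government, faith-based/NGO and private trustees).

The package turns raw facility inputs — cost ledgers over two fiscal years,
cost-centre structures, asset registers, payrolls, service statistics — into
unit costs, episode costs and national totals:

* **Annualization** — two-year averaging with a 5% inflation uplift on the
  earlier year, straight-line depreciation (equipment 10 y / medical 8 y /
  vehicles 8 y / buildings 30 y), staff time valued at full remuneration over
  220 days × 6 direct hours per year, in-kind supply imputation, and EUR
  conversion at a fixed 90.66 Ksh/€.
* **Step-down allocation** — indirect costs collect on cost centres; support
  centres (administration, laundry, kitchen) close one at a time,
  distributing their accumulated cost over the remaining centres until only
  final, patient-serving centres hold cost. Unit costs per outpatient visit,
  admission and bed-day follow by dividing each pool by its output; the
  admission/bed-day cost ratio approximates the average length of stay.
* **Episode costing** — each of the 59 essential-package conditions is
  costed as priced treatment recipe (direct) plus the indirect share of the
  facility overhead (per visit, or per bed-day × length of stay), in both
  *actual* and *normative* (expert standard) variants, with household
  outside-drug spending from exit interviews folded into unit costs.
* **Reporting** — aggregation to a stratum × input-category national cost
  matrix with exact margins, trustee and category shares, per-capita figures.
* **Scenarios** — unit costs restated at a standard 85% bed occupancy, and
  national cost as a function of coverage through a fixed/variable
  decomposition: demand scaled by m costs (F + mV)/(F + V) ≤ m, with
  optional discrete capacity-expansion blocks beyond a utilization
  threshold.
* **Synthetic data** — a seeded generator producing a full study sample
  (154 facilities: 85 government / 35 FBO-NGO / 34 private, plus the central
  ministry), calibratable to a published national cost matrix by
  deterministic rescaling.

## Worked example

```python
from khscm.reporting import load_published_matrix, share_by_trustee, share_by_category
from khscm.stepdown import UnitCost, UnitCosts, unit_cost_ratios

matrix, grouping = load_published_matrix()
print(f"grand total: {matrix.grand_total:,.0f} EUR")
print("trustee shares (%):", share_by_trustee(matrix, grouping))
shares = share_by_category(matrix)
print("staffing share:", shares["staffing"], "% of total,",
      shares["staffing_of_recurrent"], "% of recurrent")

u = UnitCosts(per_admission=UnitCost(total=12970), per_bed_day=UnitCost(total=2186))
print("district hospital ALOS proxy:", unit_cost_ratios(u)[0], "days")
```

prints

```
grand total: 694,947,102 EUR
trustee shares (%): {'public': 52, 'fbo_ngo': 17, 'private': 23, 'administration': 7}
staffing share: 37 % of total, 52 % of recurrent
district hospital ALOS proxy: 5.9 days
```

The bundled matrix is the national summary for Kenya FY2006/07: essential
health services cost 694.9 M€ in total, of which 37% is staffing (52% of
recurrent spending), 17% is incurred by faith-based/NGO facilities and 23%
by the private sector; a public district hospital admission (12,970 Ksh)
costs 5.9 bed-days (2,186 Ksh each) — the average length of stay.

From the shell, the same pipeline runs end to end on a generated sample:

```sh
khscm synth --seed 42 --out sample/
# wrote 154 facilities (public=85, fbo_ngo=35, private=34) to sample/
khscm run --sample sample/ --out report/
# report/ now holds matrix.csv, unit_costs.csv, episodes.csv, curve.csv, manifest.json
```

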