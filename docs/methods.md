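# Methods

## The two measurement methods

Both methods estimate the same quantity — weekly patient consumption of
broad-spectrum antibiotics per ward and agent, in WHO DDD units — from
different records.

**Ward stock accounting** treats the shelf as a mass balance. With
snapshots S on week boundaries (boundary *b* is the count taken at the
start of week *b*+1, after the morning doses and before the day's pharmacy
orders; boundary 0 is the pre-study count), consumption in week *w* is

    C_w = S_{w-1} − S_w + deliveries_w + loans_in_w
          − loans_out_w − discharge_takeaways_w − discards_w − returns_w

Snapshots are counted in pack units (vials, bags, tablets; fractions
allowed for partially used blister packs) and converted via the DDD
reference table; flows are recorded in DDDs. Returns to the pharmacy are
netted like discards on the ward side: stock-reducing, not consumption.

**Pharmacy sales accounting** is orders minus returns per ward × agent ×
week. Cells with no records are zero; a week where returns exceed orders is
kept negative — no floor is applied, since netting is the method's
definition.

### Missing count blocks

When counts are missing for a run of weeks (holidays), the balance equation
still determines the *block* total exactly from the two surrounding
snapshots plus the in-block flows. Each week inside the block is then
assigned the block average. The same averaging is applied to the pharmacy
series over the same weeks so the two methods stay comparable. Imputation
conserves the series total exactly; imputed weeks are flagged in the output.

### Registration intervals and pairing

Weekly values are summed into consecutive, non-overlapping intervals of
k = 1–4 weeks, starting at the first retained week. When the study window
is not divisible by k, configured weeks are omitted first (default weeks 12
and 26, the weeks with incomplete acquisition in the study this models); a
non-divisible remainder is a configuration error, never silent truncation.
One *dual registration* is one (ward, agent, interval) cell holding both
methods' totals. Cells that are zero under both methods are retained in all
statistics — with eight agents over five wards most carbapenem cells are
honest zeros, and dropping them would overstate disagreement among the
active cells' share of variance.

## Agreement statistics

**ICC.** Reliability of pharmacy data against the ward reference is the
intraclass correlation from a two-way ANOVA with the dual registrations as
random subjects and the two methods as a fixed factor (k = 2):

    MS_subjects, MS_error  →  ICC(3,1) = (MS_s − MS_e) / (MS_s + MS_e)

equivalently σ²_s / (σ²_s + σ²_e) with σ²_s = (MS_s − MS_e)/2 (floored at
zero for reporting) and σ²_e = MS_e. The *consistency* variant is the
default because a systematic level shift between pharmacy and ward figures
is the object of the separate Bland–Altman analysis; an absolute-agreement
variant, ICC(2,1), is available via `variant="absolute"`. Confidence
intervals are exact F-distribution bounds transformed through the ICC
formula (Shrout–Fleiss for consistency, McGraw–Wong with Satterthwaite
degrees of freedom for absolute agreement). The sufficiency threshold is
0.7, inclusive: ICC = 0.7 exactly counts as sufficient. Degenerate input
(zero total variance) yields an undefined ICC with a reason, never a 0 or 1.

**Bland–Altman.** Differences d = pharmacy − ward per registration; mean
difference, sd with the n−1 denominator, limits of agreement mean ± 1.96 sd
(1.96 verbatim, not a t quantile, per the convention). The per-registration
limits are converted to an interval-level DDD use range by scaling linearly
with the number of ward × agent cells summed into one interval total:

    range = mean_interval_use + n_cells × (loa_low, loa_high)

This linear scaling is an interpretation: it treats the per-cell limits as
if cell deviations added coherently, which is the reading consistent with
pairing a per-registration mean difference with an interval-total mean use.
It is an upper envelope — independent cell errors would grow as √n_cells —
so the reported percent ranges are conservative.

**Mean interval use** is ((pharmacy grand total + ward grand total)/2)
divided by the number of intervals, over retained weeks, per stratum.

## The simulator

The generator emulates the mechanism that makes the two methods disagree:
ward stock fluctuation under lot ordering. There is *no* measurement noise
— every count and record is exact — so the accounting pipeline can be held
to exact conservation: with complete flow records, ward accounting must
reproduce the simulator's true consumption to 1e-9 in every cell, and
pharmacy sales must satisfy the identity sales = stock change + consumption
+ outgoing flows − loans in, exactly. Both are enforced in tests (the
conservation check across 1000 randomized small studies).

Per ward × agent, daily: demand is drawn (default Poisson with the cell's
weekly rate / 7, in whole DDDs; optionally patient-course bursts — Poisson
admissions starting 1 DDD/day courses of geometric length, mean 7 days) and
taken from stock, with unmet demand deferred and consumed on resupply
(same-day resupply exists in the modelled hospital, so demand is never
lost). On the first day of each week the shelf is snapshotted after the
morning dose and before ordering — this timing, plus same-week delivery of
orders, is what puts a sold-but-not-yet-consumed wedge between the two
series. Ordering is reorder-point: when stock falls below the route's
threshold, one lot is drawn from the route's discrete size distribution.
Weekly loan/discard/discharge/return events are Poisson in whole DDDs,
clipped at available stock.

Default study configuration (the shape of the modelled five-ward study):

| parameter | default | rationale |
|---|---|---|
| wards × agents × weeks | 5 × 8 × 26 | the study grid; 1040 weekly dual registrations |
| weekly demand per cell | ward×class DDD totals / 26 | matches the published per-ward class totals; expected grand total ≈ 3 970 DDDs |
| 3rd-gen split (cefotaxime/ceftazidime/ceftriaxone) | 50/30/20% | within-class split unreported; fixed once |
| carbapenem split (meropenem/imipenem) | 60/40% | same |
| parenteral orders | uniform on {5..10} DDDs, reorder point 5 | small frequent orders, median 5–10 DDDs, ~14–110 orders/agent over 26 weeks |
| oral orders | {5,10,15,20,25,30,40,50} DDDs weighted (median 20), reorder point 10 | lumpy tablet orders, range 5–50, median 20 |
| flow rates (DDD/week, hospital-wide) | discard 10.5/26, discharge 18/26, loans out 14.5/26, loans in 9/26 | the published 26-week flow totals, ≈1% of use; allocated to cells ∝ demand |
| returns rate | 0 | return amounts unreported; the flow type is fully supported |
| initial stock | reorder point + 1.5 weeks of demand | free choice; avoids a transient ordering burst |
| missing blocks | weeks 10–12 and 25–26 | the study's holiday gaps; interior snapshot boundaries suppressed, block-edge boundaries kept |

The seed fully determines the output; random streams are split per
ward × agent position so adding an agent leaves other series untouched.
`degrade_to_observed` drops a fraction of the *manually* registered flows
(loans, discharge take-aways) to stress-test the accounting under
incomplete nurse registration; electronically registered discards, returns
and sales are never dropped.

What the simulator does **not** emulate: per-patient prescribing structure,
seasonal or outbreak demand trends, correlated demand between agents
(substitution), inter-ward loan pairing (loans in and out are independent,
as loans can involve wards outside the study set), pack-size constraints on
order lots, and recording errors. Passing tests therefore demonstrate the
pipeline's arithmetic and statistical machinery and the qualitative
stock-fluctuation mechanism — not that real surveillance data meets any
particular ICC.

## Numerical choices and edge cases

* Percent difference is 100 × (pharmacy − ward)/pharmacy; a zero pharmacy
  denominator is reported as missing (printed as "-"), matching how
  zero-use cells are conventionally tabulated.
* Report tables round percentages half-away-from-zero to one decimal at CSV
  serialization only; all in-memory values keep full precision and
  rounding never feeds back into computation.
* Week indexing is 1-based; interval partitions are closed on both ends;
  snapshot boundaries run 0..W.
* MS_error is clamped at zero against floating-point cancellation in the
  sums-of-squares subtraction; an exactly zero MS_error yields ICC 1 with a
  collapsed CI.
* ICC confidence bounds are ordered (low ≤ high) after the F transform.
* Reference-table lookups of unknown agents raise; they are never silent
  zeros. Duplicate agent ids or duplicate (ATC, route) pairs are rejected.

## Problem sizes in tests

The default simulated study (5 × 8 × 26) runs in ~30 ms, so the replicate
property checks use 20 full replicates; the conservation fuzz uses 1000
randomized 1-ward × 2-agent studies of 2–5 weeks. These sizes give the
trend checks comfortable resolution (the parenteral-vs-oral ICC gap at
k = 1 is ~0.6 on simulated data) while keeping the whole suite near ten
seconds.

## Known limitations

* The DDD reference values shipped with the default configuration follow
  one ATC/DDD index year; DDD assignments change between years, which is
  why they are data, not constants.
* The interval-level use-range conversion is the linear-scaling
  interpretation described above; treat the percent ranges as conservative
  envelopes.
* The DDDs/100-bed-days rate is provided as a formula only; bed-day
  censuses enter as a scalar, not a data model.
* Negative pharmacy weeks (returns exceeding orders) are legitimate inputs
  to every downstream statistic; no flooring or winsorising is offered.
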