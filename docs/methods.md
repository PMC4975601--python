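# Methods

## The cost model

The plant is described by an ordered flowsheet of unit operations — seed
fermentation, production fermentation (fed-batch *Pichia pastoris*), cell
removal, ATPS extraction, UF/DF, bulk fill — each carrying an occupancy
time, in/out volumes, a step yield, and per-batch consumable and material
demands. Product mass balance is

```
per-batch output (g) = titer (g/L) × fermenter working volume (L) × Π step yields
batches/yr           = ⌈ target output / per-batch output ⌉   (at least 1)
```

Scheduling assumes staggered trains: throughput is limited by the longest
single stage (90 h production fermentation), giving ⌊330 d × 24 h / 90 h⌋ =
88 batches/yr per train. When a scenario or Monte Carlo draw needs more
batches than the configured trains can schedule, the evaluation either
raises an infeasible-schedule error (deterministic contexts) or prices in
the minimum number of extra parallel trains and flags the result
(sensitivity rows and Monte Carlo draws, which must never be silently
dropped — the overflow corner is exactly the expensive region of input
space). Capital scales with the train count; labor does not (one staff
complement runs the site), a deliberate simplification.

Annual cost splits into five categories:

| category    | model                                                        |
|-------------|--------------------------------------------------------------|
| capital     | Σ installed equipment × facility multiplier 4 / 10 yr × trains |
| consumables | batches × per-batch demand × unit price × deviation multiplier |
| materials   | same, for media/chemicals/buffers                            |
| labor       | Σ headcount × wage (role-level, plant-wide)                  |
| other       | QC per batch × batches + 5% overhead on direct cost          |

The material-cost deviation (a signed %) applies only to the designated
dominant items: seed/production fermentation media and UF/DF membranes.
Per-unit-operation attribution covers consumables + materials only;
capital and labor are plant-level (their allocation to stages would be
arbitrary).

**CoG/g denominator.** Two modes are supported: `produced` (batches ×
per-batch output; the default) and `target` (the nominal annual demand).
They differ by the ceiling slack of the batch count, which has a real
consequence for shape properties: CoG/g is *exactly* nonincreasing in
target output in produced mode (fixed costs spread over every gram made)
and *exactly* nonincreasing in titer and DSP yield in target mode (batch
count and hence variable cost can only fall); in the respective other mode
each property holds only up to a one-batch ceiling quantum. Property tests
assert each monotonicity in the mode where it is exact, and the Monte
Carlo envelope test bounds the fixed- and variable-cost per-gram terms
separately rather than assuming joint monotonicity.

**Staffing.** Headcount is sized so labor is 13% of total annual cost.
With overhead rate *r* coupling labor into `other`, the fixed point has the
closed form `labor = s·N / (1 − s(1+r))` with *N* the labor-independent
cost. Headcount is allocated operator : supervisor : QA : QC = 8 : 1 : 2 : 2
and rounded per role; at base this gives 48/6/12/12 staff and a realized
share of 13.09%. Wage-location scenarios swap the whole four-role wage
table atomically.

## Calibration

The closed commercial cost database behind the published base case cannot
be reproduced, so five synthetic constants are free: equipment cost scale,
media price ($/L), UF/DF membrane price, QC cost per batch, and fermenter
working volume. `calibration.calibrate()` adjusts them within bounds by
bounded Nelder-Mead on a relative least-squares objective (base CoG/g vs
$843, labor share vs 13%) with hinge penalties enforcing capital ≥
consumables ≥ every other category and UF/DF dominance of the operation
attribution. The search is derivative-free and fully deterministic; if the
starting constants already satisfy every anchor (as the shipped defaults
do: CoG/g $842.50, share 13.09%), calibration is a fixed point and returns
them unchanged. An infeasible bound set raises a diagnostic naming each
violated anchor or ordering.

The shipped default prices were chosen once, by hand, to be plausible for
a 2000 L microbial plant (e.g. $8/L complex medium, $10k per UF/DF
cassette with 8 cassettes/batch reflecting the large ATPS volumes UF/DF
must process, $21.25M installed equipment) and to land on the anchors; the
calibration machinery exists so a user who edits the flowsheet or prices
can re-anchor the model.

## Scenario analysis

Worst/base/best values follow fixed rules: titer and DSP yield at mean ∓ 1
standard deviation (0.242 ± 0.134 g/L; 95.8 ± 1.1%), material cost at
±25%, target output halved/doubled (12.8 / 25.6 / 51.2 kg/yr), wages by
location (US worst, UK base, Mexico best). The tornado ranks parameters by
the largest one-sided |ΔCoG/g| (switchable to worst-to-best range; the two
agree on this model). Worst/best are effect-directed, not numeric: +25%
material cost is the worst case.

## Monte Carlo

Titer, target output and material deviation are drawn independently each
run — no correlation information exists to justify anything else — from
triangular(min, mode, max) distributions built from the scenario bounds.
Sampling is by the closed-form inverse CDF; the generator is a single
seeded PCG64 stream supplying one uniform per parameter per run in
run-major order, so a run count and seed fully determine the result. The
after-optimization titer distribution is triangular(3.00, 5.44, 7.88),
i.e. mode 5.44 with min/max one reported standard deviation either side,
mirroring the mean ∓ SD convention used for the scenario bounds.

**Convergence.** After each run the running mean of the CoG/g series is
updated; convergence is declared at the first run where its relative
change has stayed ≤ 1% for 50 consecutive runs (window 50, tolerance 0.01;
a constant series therefore converges exactly at run 50). Both
configurations stabilize at roughly runs 80–120 across seeds, comfortably
inside the 300-run standard adopted here, which the package keeps as
`max_runs` so summaries are computed on a fixed sample size.

## Linear meta-model

OLS of CoG/g on the three sampled inputs with an intercept (statsmodels
behind the scenes; the test suite checks the fit against an explicit
normal-equations solve). Standard errors use the unbiased residual
variance; p-values are two-sided t at n − 4 degrees of freedom; no
multiple-testing correction is applied. The significance screen is
`p < α` with α = 0.01. Driver ranking weighs each coefficient by the width
of its sampling support, |βᵢ × span(xᵢ)|, so $/(g/L) and $/(kg/yr) become
comparable dollar impacts; because optimization widens the titer support,
the before- and after-rankings use their own spans. The model is
deliberately first-order: the true cost surface is convex in 1/titer, and
the sizeable residuals at low titer are part of why the material term is
detectable before optimization (large variable-cost share) and not after.

## What the synthetic fixtures do and do not emulate

The fixtures reproduce the *structure* reported for this process: the
published process parameters, scenario bounds and wage tables verbatim;
batch counts (56 at base) and category ordering; the dominance of UF/DF
consumables driven by ATPS volumes. They do not reproduce any real
supplier's prices, equipment list or QC cost model — those are the closed
database's content. Consequently tests and the acceptance script treat
absolute downstream magnitudes (Monte Carlo means, regression coefficient
sizes) as model-specific, and assert only the reproducible layer: the
worked arithmetic, the calibration anchors, and the signs, orderings,
asymmetries and significance flips of the analysis chain. Passing tests
show the open model behaves like the reported one *given* a cost surface
with the anchored shape — not that these dollars are what a real plant
would spend.

## Numerical choices and degenerate inputs

* Batch count uses exact-integer guard logic so a target equal to k
  batches yields k, not k+1, despite float ceiling; a vanishing target
  still costs one batch.
* Triangular distributions admit a degenerate point support (min = mode =
  max), which reproduces the deterministic base case run-for-run — the
  natural smoke test of the MC plumbing.
* A degenerate sampling distribution collapses a design-matrix column; the
  OLS front end detects the constant column and names it rather than
  returning a near-singular solve.
* The titer-range reporting rounds half-to-even on decimal values
  (0.242 × 22.5 = 5.445 → 5.44), avoiding the float artifact that makes
  naive rounding print 5.45.
* The fold-scaled titer SD (0.134 × 22.5 = 3.015 g/L) differs from the
  reported 2.44 g/L; both are exposed, and the after-optimization fixtures
  use the reported value.

## Problem sizes

Monte Carlo runs are 300 per configuration (the adopted standard; also the
regression sample size). Sampler-moment checks use n = 10⁵ draws; OLS
calibration checks use 500–600 replicates at n = 300. The whole test suite
plus acceptance script runs in well under a minute.

## Known limitations

* Capital and QC treatments are simple (straight-line, flat per batch);
  no depreciation schedules, NPV/IRR or business-case factors — product
  pricing, storage, cooling and transport are out of scope by design.
* No ATPS partition-physics: step yields are inputs, so the model cannot
  say how recovery would respond to phase-system changes.
* Labor does not scale with train count or batch count; at high overflow
  the labor share therefore understates a real multi-train site.
* The three Monte Carlo inputs are sampled independently; correlated
  supply-price/titer shocks would widen the CoG/g distribution.
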