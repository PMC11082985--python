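# Methods

`indexroc` evaluates a quantitative diagnostic marker test and, alongside
it, a qualitative (visually read) version of the same assay, over a grid of
concentration cut-offs. This note records the statistical model, the
numerical procedures, the defaults and the design choices, and what the
synthetic data generator does and does not emulate.

## Model and quantities

A cohort consists of records `(value, diseased)`: a marker concentration in
µg/L and a binary gold-standard disease label. Dichotomising at a cut-off
`c` produces the confusion counts (TP, FP, TN, FN), from which:

- sensitivity `Se = TP/(TP+FN)`, specificity `Sp = TN/(TN+FP)`;
- predictive values `PPV = TP/(TP+FP)`, `NPV = TN/(TN+FN)`;
- Youden's index `J = Se + Sp − 1` (the SS summary index);
- Predictive Summary Index `PSI = PPV + NPV − 1` (the PV analogue);
- reciprocal indices `1/J` and `1/PSI`: the number of persons who must be
  examined to correctly detect one diseased person, respectively to
  correctly predict one diagnosis. Both the raw real and the
  nearest-integer person count are reported, because the literature mixes
  the two conventions.

At the cohort's own prevalence `p`, the empirical predictive values are
algebraically identical to the Bayes transform

    PPV = Se·p / (Se·p + (1−Sp)(1−p)),
    NPV = Sp(1−p) / (Sp(1−p) + (1−Se)p),

an identity the test suite asserts to 1e−12; `bayes_predictive_values`
also lets the user move the (Se, Sp) profile to any other prevalence.

**Positivity convention.** A value is test-positive when it is **≥** the
cut-off (a lateral-flow line develops at or above a preset concentration).
The comparator is configurable (`ge`/`gt`) everywhere a threshold is
applied. With `ge`, Se is non-increasing and Sp non-decreasing in the
cut-off.

**Undefined values.** Any 0/0 rate (e.g. PPV when no subject tests
positive, routine at the high-concentration tail) is carried as an explicit
`None`, never NaN or 0. Curve builders drop such points, record them on
the curve's `dropped` list and log them; they are never interpolated
through.

## Curves

All curve families are evaluated on a user-supplied grid of preset
concentrations — the default is `{5, 7.5, 10, 30, 50, 90, 110, 250, 300}`
µg/L — rather than on all empirical thresholds; an empirical-grid mode
(every distinct observed value) exists and is what the ROC oracle tests
use. Grid values below the detection floor (default 0.5 µg/L, the
smallest concentration a photometric reader can report) are clipped up to
the floor.

Every plotted point carries its generating cut-off and full metric bundle,
so the curves are lossless: the traditional ROC plot's discarded threshold
information is retained and rendered as point labels (decimated to ≤ 25
labels on dense grids).

- **CDA curves**: Se, Sp, PPV, NPV against cut-off.
- **SS-ROC**: `(1−Sp, Se)`. Its AUC is computed by the trapezoidal rule
  over the grid points *plus two virtual anchors* (0,0) and (1,1) — the
  threshold → ∞ and threshold → floor limits. Without the anchors a
  perfectly separated cohort on a two-point grid would integrate to 0;
  with them it integrates to 1 and a label-permuted cohort to ≈ 0.5.
  Duplicate x values collapse to their maximal y before integrating.
- **PV-ROC**: `(1−NPV, PPV)`. This curve has **no AUC** — its axes do not
  span [0, 1] and at low prevalence it occupies a narrow x-interval — and
  the object enforces that by raising on `auc()`. Its cut-off direction is
  opposite to the SS-ROC's.
- **Index-ROC**: `J` vs `1−Sp` and `PSI` vs `1−NPV`; these may cross the
  plot diagonal and likewise carry no AUC.

## Unified analysis

The **index cut-off diagram** plots `J(c)` and `PSI(c)` against `c` on one
axis. Both curves are treated as piecewise-linear in the raw cut-off
domain — matching how values are read off a linear point plot; a log-domain
option was considered (the grid spans 0.5–300 µg/L) and rejected as the
default because the graphical procedure being formalised is linear.

**Unified optimal cut-off.** Every sign change of `d(c) = J(c) − PSI(c)`
on the union of the two node sets (restricted to the common span) is
bracketed and bisected with Brent's method to 1e−6 µg/L. All crossings
are reported; the primary one is the crossing with the greatest common
index value. Degenerate cases are explicit results, not silent choices:
identical curves → `"coincident"`; no sign change → `"no-crossing"` with
the node minimising `|d|`. No extrapolation beyond the grid span is ever
performed — the sparse-count tail (TP and FP counts of order 10 at
250–300 µg/L in the motivating data) makes extrapolated indices
meaningless.

**AOX (area over the x-axis).** The integral of `max(index, 0)` over a
cut-off range (default: full span), units index·µg/L, plus a normalized
form (area / range width = mean index level). Negative-index regions
contribute 0 by default — below-chance performance should not offset
diagnostic value in an effectivity summary — and the clipping is
switchable (`clip_negative=False`). Integration is an exact trapezoid on
the piecewise-linear interpolant with zero-crossing breakpoints inserted,
so additivity over subranges holds to 1e−12 and the result matches a
1e−3-step Riemann oracle. A `unified_min_curve` helper exposes
pointwise `min(J, PSI)` for unified-min AOX summaries.

**Reciprocal diagrams** map both curves through `1/index`, dropping
non-positive nodes (no person interpretation exists at or below chance).
Because `1/x` is strictly decreasing, the J/PSI crossing is preserved —
*exactly* when the crossing lies on a shared grid node. Between nodes the
reciprocal of a linear interpolant is not the interpolant of the
reciprocals, so on coarse grids the reciprocal-diagram crossing can shift
within the bracketing interval; the discrepancy shrinks with grid
refinement. The tests pin the node-exact case and document this limit.

## Qualitative bridge

A visual test with observed `(Se, Sp)` (or `(PPV, NPV)`) is assigned an
*implied* concentration cut-off by inverting the reader's piecewise-linear
CDA curves: exact node hits return the node cut-off; otherwise each
straddled segment is solved linearly. The two metrics of a pair generally
imply two cut-offs; both candidate lists are always reported, the
representative pair is the one minimising the disagreement between the
metrics (ties toward the lower cut-off, relevant on plateaus of the
empirical step curves), and the combined estimate is their geometric mean
— transparency instead of a silent average, since the concentration scale
is ratio-like and spans two orders of magnitude. Values outside the
curve's y-range raise (no extrapolation). Diagnostic gain of the reader
over the visual test is the signed difference in percentage points at a
reference cut-off; deficits are not clamped.

## Synthetic data generator

`generate_cohort` draws the diseased and disease-free groups from
log-normal distributions, clips at the detection floor (0.5 µg/L), and
fixes the class sizes exactly — defaults 91 diseased / 1152 disease-free,
prevalence 0.073, the regime of the bladder-cancer worked example. The
PRNG is NumPy's `default_rng` (PCG64), fully determined by the spec's seed.

Default distribution parameters (ln-scale): diseased μ = 3.66, σ = 1.60 —
the unique solution of Se(5 µg/L) = 0.9 and Se(300 µg/L) = 0.1, so the
preset grid sweeps sensitivity from ≈ 0.9 to ≈ 0.1; disease-free μ = 1.80,
σ = 0.80, placing Sp(7.5) ≈ 0.64 and Sp(10) ≈ 0.77 near the worked
example's printed reader values. `group_se_sp` exposes the closed-form
population (Se, Sp) of the generating mixture, which the Monte-Carlo
sanity tests compare against empirical curves (3-binomial-SE bands at
10,000 per group).

What the generator emulates: heavy right skew, broad between-group
overlap, a hard detection floor, exact low prevalence. What it does not:
assay-specific measurement error, reader quantisation, within-patient
repeat variability, covariate structure (stage, grade), or the worked
example's actual patient-level values (which are not public). Passing
tests therefore demonstrate correctness of the *procedures* on a
realistic marker regime, not reproduction of any particular study's curve
shapes.

`worked_example_table` ships the published per-cutoff summary values of
the worked example so the curve and diagram code can be driven from
printed numbers alone. One reader predictive-value row (250 µg/L) is
internally inconsistent as printed — its PSI does not equal PPV + NPV − 1
and its TP/FP counts imply a different PPV — and is carried verbatim with
`consistent=False`; the package flags, never corrects, published numbers.

## Problem sizes and numerical settings

Default analyses run the 1243-record study-sized cohort on the 9-point
preset grid. Property suites use 50–80-record random cohorts with their
full empirical grids; Monte-Carlo checks use 10,000 per group; chance-AUC
checks use 4,000–20,000 records with a ±0.03 band. Crossing bisection:
xtol 1e−6 µg/L; coincidence tolerance 1e−12; exact-node tolerance in
inverse lookup 1e−12.

## Known limitations

- Indices weight Se against Sp (and PPV against NPV) equally; no
  cost-weighted variants.
- No confidence intervals or significance tests for Se/Sp/PV, the AUC, or
  the crossing location.
- The unified cut-off inherits grid resolution: between nodes it is a
  property of the linear interpolants, not of the underlying continuous
  curves (the convergence test shows the error shrinking with refinement).
- Localisation of the qualitative test on the quantitative scale assumes
  the CDA curves are monotone near the solution; on plateaus the implied
  cut-off is reported with all candidates rather than a unique value.
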