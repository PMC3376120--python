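# Methods

## Survival model and estimator

`survfig` analyses right-censored time-to-event data: per subject an
observed time and an event indicator (`event_code`, default 1, means the
event occurred; any other finite status value is censored). Time units are
arbitrary but must be shared by all subjects; times must be finite and
non-negative.

The per-stratum survival function is the product-limit (Kaplan–Meier)
estimate S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i) over the distinct event times
t_i. Conventions, chosen where the underlying mathematics is silent:

- **Ties between events and censorings at the same time**: the event is
  processed first, i.e. a subject censored at t is still in the risk set
  n_i at t. This is the standard convention and is what makes our output
  agree with other implementations to machine precision.
- **At-risk counting on a grid** (the in-figure table): a subject counts as
  at risk at grid time t when their observed time is ≥ t, so someone
  exiting exactly at a tick is still counted there — consistent with the
  n_i bookkeeping above. Whether a borderline subject "should" appear at a
  tick is a display convention, not an estimand; this one is documented
  and tested.
- **No events at all** yields S ≡ 1 (a valid flat curve), not an error;
  zero subjects is an error.
- **No confidence intervals**: the figures carry point estimates plus
  number-at-risk tables; Greenwood variance and confidence bands are out
  of scope by design.
- For display, curves extend horizontally from the last observed time to
  the x-axis maximum. This is drawing, not extrapolation: no statistical
  claim is made beyond the last observation, and `survival_at` is defined
  from the estimate itself (right-continuous step lookup).

## Logrank test

At each distinct event time with d events among N at risk, group g
contributes observed d_g and expected d·n_g/N; the covariance accumulates
the tie-corrected hypergeometric form

V_gh = d (N − d)/(N − 1) · (n_g/N) (δ_gh − n_h/N),

skipping times with N = 1 (zero variance). The statistic is the quadratic
form of the first k − 1 components of O − E against the matching covariance
block, using a Moore–Penrose pseudoinverse so degenerate strata (e.g. a
group exhausted before the others' events) cannot produce a singular solve;
with a full-rank block this equals the ordinary inverse. The statistic is
referred to chi-square with k − 1 degrees of freedom.

Pairwise mode runs the plain two-group test for each unordered pair in
lexicographic order and reports **unadjusted** p-values — the conventional
in-figure presentation. When the pairwise family is used inferentially, a
multiplicity correction (Bonferroni, Holm) should be applied by the reader;
the numbers printed are deliberately raw.

P-values print in fixed point with a configurable number of decimals
(default 4, range 1–10). A value below half the print resolution
(10^−digits/2) would round to an impossible exact zero, so it is clipped to
`<10^−digits` (e.g. `<0.0001`). Whether to clip or print `0.0000` was an
open choice; clipping is the statistically honest display.

## Filter language

Filters are parsed by a hand-written recursive-descent parser over the
token set `< <= > >= = ~=` (with `==`/`!=` as synonyms), `& | ~` (word
forms `AND OR NOT`, case-insensitive), arithmetic `+ − * /` and
parentheses. Precedence, loosest to tightest: OR, AND, NOT, comparison,
additive, multiplicative, unary minus; all binary operators associate left.
Comparisons are non-associative (`a < b < c` is a syntax error rather than
a silent chain). Design choices:

- A comparison involving a missing value (NaN) evaluates **false**: a
  filter never keeps a row it cannot judge.
- `=` is exact numeric equality; documentation steers users toward
  inequalities for continuous variables.
- A filter whose top level is numeric (e.g. `a+1`) is a type error at
  evaluation; only boolean expressions subset rows.
- A filter that removes every row is an error (`EmptyFilterResultError`):
  analyses of zero subjects must not proceed silently.

The pretty-printer emits fully parenthesized text and round-trips:
`parse(unparse(e)) == e`, property-tested over random ASTs.

## Plot specifications and rendering

A `PlotSpec` stores the *location* of its data plus everything needed to
re-render the figure; serialized specs never contain survival observations,
so they are safe to share and version. The on-disk format is JSON with a
`format_version` field (currently 1); loading rejects unknown fields by
name and foreign versions explicitly, because a silently dropped field in a
figure recipe is a corrupted figure.

Axis resolution: explicit settings with max > min and step > 0 give the
exact tick sequence min, min+step, …, max; anything degenerate (the
all-zero default included) falls back to automatic "nice" ticks over the
data range. A y maximum above 1 switches the axis to percent: displayed
step values are scaled by exactly 100 while life tables and tests are
untouched. Legend, test box and information text are positioned in data
coordinates, which keeps saved positions meaningful when the figure size
changes.

Rendering is two-stage: a structured *render plan* (step polylines, censor
marks at (censor time, current step value), at-risk rows aligned to the x
ticks, legend and text boxes) is built first and is what the tests assert
against; matplotlib then draws the plan. The at-risk grid is the x tick
sequence, drawn inside the axes above the x axis, one row per group in the
group's color, the t = 0 column equalling the group size. Vector output is
deterministic — a fixed SVG hash salt and no embedded timestamps make
identical inputs produce byte-identical SVG; raster formats (png, jpg, tif)
and pdf/eps are smoke-tested for validity only. The default palette is a
fixed eight-color list starting with black, cycled for more than eight
levels.

## Batch queue

A queue renders spec files strictly in order into one directory, output
named `<spec stem>.<format>`. Errors are logged per spec and processing
continues (a `fail_fast` flag flips this); the log has exactly one entry
per input spec and always ends with the sentinel `Finished`, so a consumer
can distinguish "finished with errors" from "crashed". Re-running a queue
overwrites its outputs and reproduces the log.

## Simulator

The generator draws, per subject, an event time T_e ~ Exponential(rate
λ_e) and an independent censoring time T_c ~ Exponential(λ_c); the observed
time is min(T_e, T_c) and the status records whether the event came first
(a tie, probability zero, counts as an event). Closed forms used in
validation: P(censored) = λ_c/(λ_e + λ_c), and each clock's rate is
consistently estimated by its outcome count over total observed follow-up
(the exponential MLE).

The default configuration is the package's reference study design: four
entities of 110, 120, 130 and 70 subjects, event rates 0.02, 0.02, 0.02
and 0.04 per time unit, shared censoring rate 0.04, group labels 1, 2, 3, 3
and filter labels 1, 1, 1, 2. With these values roughly two thirds of the
baseline entities are censored (0.04/0.06), group 3's curve declines faster
than groups 1–2 because of its embedded higher-risk subset, and filtering
with `filtervar<2` leaves three identically distributed groups — a built-in
null used to calibrate the logrank test.

Reproducibility: a single root seed feeds a `SeedSequence`; each entity
draws from its own spawned substream, so appending an entity never perturbs
earlier entities' draws. Times are written to `.dat` files with shortest
round-tripping decimals, so file round-trips are exact.

What the simulator does **not** emulate: covariate-dependent or
time-varying hazards, staggered accrual, informative censoring, or
non-exponential event distributions. Passing calibration under this design
therefore demonstrates correctness of the estimators and the test under
proportional constant hazards with independent censoring — not robustness
to violations of those assumptions.

## Validation suite sizes

The statistical checks run at sizes chosen to make their tolerances
meaningful while keeping the suite quick to iterate on: rate recovery
averages 200 replicate datasets (±10% relative around the configured
rates); the null calibration uses 2000 replicates of the filtered design
(type-I error 5% ± 1.5% at α = 0.05, Kolmogorov–Smirnov distance to the
uniform < 0.05); the signal check uses the median of Ŝ₃(35) − Ŝ₁(35) over
200 replicates; estimator equivalence compares 200 random small datasets
(n ≤ 30, heavy ties, random censoring) against an independent reference
implementation at 1e−10.

## Known limitations

- Only the logrank test is provided — no Wilcoxon/Tarone–Ware weights,
  stratified or trend tests, and no hazard-ratio estimation.
- Columns are numeric-only; string-valued factors must be coded as numbers.
- SPSS `.sav` / SAS `.xpt` readers are not built in; convert to `.dat`/CSV
  or load via an ecosystem reader into a DataFrame first.
- Median survival, competing risks and left truncation are out of scope.
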