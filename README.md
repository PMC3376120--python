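# survfig

Kaplan–Meier survival curves, logrank tests and reproducible publication
figures — as a scriptable Python library with a thin command line.

`survfig` is for analysts who produce *series* of survival figures: clinical
and epidemiological studies where the same analysis is re-run under different
filters, styles and output formats. Instead of a GUI session, every figure is
described by a small, data-free JSON **plot spec** (data location, variable
roles, filter string, per-group styles, axes, legend, tests) that can be
saved, diffed, and batch-re-rendered.

## What it computes

For right-censored times with d_i events among n_i subjects at risk at the
distinct event times t_i, the survival function per stratum is the
product-limit estimate

    S(t) = ∏_{t_i ≤ t} (1 − d_i / n_i)

with the standard tie convention (events before censorings at a shared
time). Strata are compared with the logrank test: at each event time the
observed deaths per group are accumulated against their hypergeometric
expectation d·n_g/N with tie-corrected covariance; the statistic is
chi-square with k − 1 degrees of freedom. Pairwise comparisons report the
plain two-group test per pair, with p-values printed at a configurable
fixed-point precision (default 4 decimals; values below the resolution are
shown as `<0.0001`).

Around the statistics sit:

- a **filter language** (`"filtervar<2"`, `"(a>1) & (b<=3)"`, …) for
  subsetting before analysis,
- **figures** with step curves, censor tick marks, in-figure number-at-risk
  tables aligned to the x ticks, legends and p-value boxes positioned in
  data coordinates, and automatic percent mode when the y maximum exceeds 1,
- a **batch queue** that renders saved specs into a directory
  (svg/pdf/eps/png/jpg/tif) and logs each one, ending with `Finished`,
- a **simulator** of grouped exponential event times with independent
  exponential censoring (competing clocks), used throughout the test suite
  to calibrate the statistics.

## Worked example

```sh
python examples/simulate_and_estimate.py
```

prints (seed 0 of the default 430-subject, three-group design):

```
simulated 430 subjects, variables: ['timevar', 'statusvar', 'factorvar', 'filtervar']
group 1: n = 110, events = 30, S(35) = 0.533
group 2: n = 120, events = 36, S(35) = 0.405
group 3: n = 200, events = 77, S(35) = 0.423
```

S(35) is each group's estimated probability of remaining event-free past
t = 35. Group 3 contains an embedded high-risk subset (70 of its 200
subjects have double the hazard), so across replicates its curve declines
fastest; any single draw is noisy. Removing that subset with the filter
string `filtervar<2` (see `examples/filter_and_test.py`) leaves three
identically distributed groups, and the pairwise logrank p-values behave
like null draws:

```
filter (filtervar < 2) removed 70 of 430 rows
factorvar = 1, 2: chi2 = 2.082, p = 0.1491
factorvar = 1, 3: chi2 = 0.565, p = 0.4522
factorvar = 2, 3: chi2 = 0.409, p = 0.5224
```

`examples/figure_from_spec.py` builds the full greyscale publication figure
(colors `#000000`/`#808080`/`#C0C0C0`, x axis 0–100 step 20, censor marks,
number-at-risk table, legend at data coordinates (70, 0.5)), and
`examples/batch_queue.py` re-renders saved specs in batch.

The same capabilities are available from the shell:

```sh
survfig simulate --out example.dat --seed 1
survfig analyze example.dat --time timevar --status statusvar \
        --factor factorvar --tests pairwise --filter "filtervar<2"
survfig draw --spec example.kmspec.json --out example.svg
survfig queue example.kmspec.json example_filtered.kmspec.json \
        --out figures --format svg
```

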