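# Methods

This note documents the models, conventions and design choices behind
`coralsource`: what each stage computes, which knobs matter, what the
synthetic study system does and does not emulate, and where the method's
limits lie.

## Thermal-regime metrics

All metrics operate on per-reef SST series (daily with optional min/max, or
weekly means). Date windows are half-open `[start, end)`; "2014 to 2016"
means 2014-01-01 up to but excluding 2017-01-01. Defaults:
`SST_av.pre` over 2014–2016, `SST_av.post`, `SST_stdev` and `DTR` over
2013–2018, with the climatological baseline also 2013–2018. All windows
are `MetricConfig` keys because window inclusivity and baselines are
conventions, not physical facts.

Anomaly machinery follows the NOAA Coral Reef Watch family of definitions:

* **Climatology** — monthly and ISO-calendar-week means over a baseline of
  at least two full years; the **MMM** (maximum monthly mean) is the
  warmest month's mean and anchors HotSpots.
* **DHW** — trailing 12-week sum of HotSpots (weekly SST − MMM) that reach
  1 °C. Window length and threshold are config keys.
* **TSA_DHW** — the same accumulation against the warmest *weekly*
  climatological mean; `TSA_DHW_stdev` is the sample standard deviation of
  that accumulated series over the analysis window.
* **SSTA frequency** — weeks at least 1 °C above their calendar-week
  climatological mean, counted per complete calendar year;
  `SSTA_Freq_stdev` is the sample standard deviation of the yearly counts.
  The 1 °C threshold is inherited convention and configurable.
* **Experiment heat dose** — a constant exposure of T °C for d days above a
  reef's MMM accumulates `max(0, T − MMM) · d/7` °C-weeks. This is a
  deliberate linear convention: a ramp-and-hold tank exposure has no
  weekly satellite cadence, so the 1 °C HotSpot gate is not applied.

Sample (n−1) standard deviations are used throughout, matching the default
of mainstream statistics environments. Daily series aggregate to weekly by
ISO-week mean with incomplete weeks dropped. Latitude is stored as positive
degrees south.

## Survival summaries

Larval survival is per-well: 100 × final/initial (20 larvae per well), with
group means and standard errors over replicate wells. Juvenile survival is
individual: the reported percentage divides individuals alive at the final
timepoint by all individuals at risk — the product-limit bookkeeping
convention in which the tabulated "events" are the survivors; censored
individuals stay in the denominator unless explicitly dropped. Its SE uses
the binomial approximation 100·√(p(1−p)/n), a documented choice where no
canonical formula exists for percent-survival bars. Kaplan–Meier curves
come from `lifelines`. Pairwise comparisons are two-sided Wilcoxon rank-sum
tests — exact null distribution for small tie-free samples (both n ≤ 12),
otherwise the tie-corrected normal approximation — with Bonferroni
adjustment (p·m capped at 1). A degenerate pair (a single repeated value on
both sides) reports p = 1 with a flag rather than failing.

The tolerance "boost" of heat-surviving groups is the exposure temperature
minus the reef's expected summer maximum (its MMM), for reefs whose
offspring exceed a survival criterion at the elevated treatment
(default > 50 %), also expressed in DHW via the linear dose convention.

## Boosted survival model

`BoostedSurvival` regresses offspring survival under heat (per-well larval
percent, or 0/100 per juvenile) on the seven metrics of the **maternal**
reef — the maternal link reflects the stronger maternal contribution to
early-life traits, and means hybrid crosses carry only the mother's
environment. Fitting is classic stochastic gradient boosting for squared
error: start from the response mean; each iteration draws `bag_fraction`
of rows without replacement, fits a small least-squares tree to their
residuals, and adds it scaled by the shrinkage.

Conventions follow the R `gbm` lineage:

* `interaction_depth` caps the number of **splits** per tree, grown
  best-first by squared-error reduction (not a depth limit);
* missing feature values route to the majority child, no surrogates;
* **relative influence** is each predictor's share of total squared-error
  reduction across all splits, normalized to 100 % (a split-count variant
  exists but is cruder — split counts ignore how much a split explains);
* out-of-sample R² is 1 − SSE/SST on held-out data and may be negative.

Defaults (500 trees, shrinkage 0.1, depth 5, ≥10 obs/node, 50 % bagging)
are ordinary choices for small ecological tables. The *pipeline* default
for the envelope-reduction stage is different — 2500 additive stumps
(depth 1, bagging 0.8): the reduction to a univariate polynomial presumes a
marginal signal, and deeper trees can reconstruct an individual reef's
identity from two splits on correlated metrics, draining influence from the
true driver and flattening the partial dependence. With only five reefs
that leakage is material; stumps suppress it.

One seed drives bagging, fold assignment and grid search through
independently derived streams (`derive_seed`), so any component re-runs
identically in isolation. Cross-validation supports repeated k-fold,
k-fold, bootstrap (out-of-bag testing) and leave-one-out; per-fold R² is
undefined for singleton folds, so the headline statistic pools all held-out
(observation, prediction) pairs, which is well defined for every scheme.
Grid-search tuning minimizes pooled CV RMSE on a shared fold stream with
ties kept in grid order. Leave-one-reef-out removes every row whose
maternal reef matches the held-out reef — the sharpest test of
extrapolation to unsampled reefs.

## Intrinsic-resistance equations and envelopes

Partial dependence is computed exactly as its definition: for each grid
value g spanning the observed feature range, the mean model prediction with
that feature set to g in every training row. No interpolation shortcuts —
the brute-force row × grid average is the implementation, so the oracle
equivalence in the tests is exact to the floating-point contract.

A polynomial of degree 3–5 is least-squares fit to the curve on its grid;
the selected degree is the smallest whose R² is within 0.005 of the best
candidate's — the simplest equation that explains the curve essentially as
well. Survival is modelled as a function of the environmental metric
(p = f(environment)), matching how the response surfaces are read; the
reverse parameterization is not meaningful for envelope solving. Roots of
p(x) − threshold are taken from the companion matrix (imaginary parts
below 1e−8 discarded); sign analysis at cell midpoints yields the closed
envelope intervals, never extrapolated beyond the observed range, with the
90 % threshold configurable. The optimum is the global maximum over
stationary points plus endpoints. A constant curve yields a flagged
degree-0 model; too few grid points reduce the degree with a flag.

## Reef selection

A catalogue reef qualifies for a model when its metric value lies inside
the envelope (closed bounds, so values exactly at a root count). Multiple
models combine under `any` (union — the headline count) or `all`
(intersection); the de-duplicated union across model combinations and its
fraction of the catalogue are reported. An optional grid-snap merges
closely adjacent selected locations into shared lat/lon cells for
counting; it is off by default because any merging radius is a reporting
choice — the catalogue's own reef identifiers define uniqueness.

## The synthetic study system

The generator emulates the experimental design end to end:

* **Five source reefs** spanning a warm low-latitude to cooler
  high-latitude gradient (annual means 26.3–28.6 °C, seasonal amplitudes
  2.2–3.2 °C, daily ranges 0.35–1.10 °C, distinct yearly anomaly
  schedules). Daily means follow an annual cosine peaking in mid-February
  (Southern Hemisphere) plus Gaussian noise; min/max sit symmetrically
  `daily_range` apart; anomalies are planted on whole ISO weeks (distinct
  across years while possible) so weekly aggregation and yearly counts see
  them exactly. Planted-week anomalies shift the self-computed climatology
  by magnitude/n_years; recovering exact yearly counts therefore needs
  magnitude ≥ threshold·n/(n−1), which the defaults satisfy.
* **The 25-cross design** (5 purebred, 20 hybrid, ordered egg × sperm) and
  the 24-tank juvenile layout (4 symbiont treatments × 2 temperatures × 3
  replicate tanks, three-well plates, individually scored juveniles coded
  2 = alive / 1 = dead, censoring optional and off by default).
* **Known truth**: heat survival is a clipped quadratic in the maternal
  reef's `TSA_DHW_stdev`, peaking at 0.98 at 1.2 °C-weeks with a true
  ≥90 % band of 0.78–1.62 °C-weeks, plus 0.02 probability-scale unit
  noise; controls survive at ~0.96 (larvae) and ~0.85 (juveniles),
  mirroring typical non-stress survival. Larval wells are Binomial(20, p);
  juveniles are Bernoulli(p).

The fixed profile table is constructed for identifiability: six metrics
share a realistic collinear gradient, while the driver varies independently
of it, the extreme-survival reefs sit interior in every non-driver metric
ordering, and no non-driver reef-partition coincides with an informative
driver split. Without these properties a unimodal response over only five
support points is not attributable to its driver by any tree ensemble —
a structural limit of five-reef designs, not of the implementation.

What the generator does **not** emulate: genetic or allelic structure,
symbiont community dynamics, spatial ocean physics, tank micro-environment
effects (a tank-level random effect exists but defaults off, since the
within-cross variance structure is not constrained by data), or
measurement error in scoring. Passing recovery tests therefore show the
chain is correct and identifiable under these conditions; they do not show
that five real reefs identify real drivers among correlated real metrics.

## Problem sizes and numerics

Recovery experiments use 25 crosses × 6 wells (150 observation units) over
30 seeds; cross-validation comparisons use 120 smooth synthetic rows and
150-tree models — sizes at which the full chain, including leave-one-out,
runs in minutes on one CPU while leaving the statistics stable. Split
search requires strictly positive gain (> 1e−12) and child sizes
≥ `min_obs_in_node` including majority-routed missing rows; split gains are
computed on non-missing rows only. Polynomial root tolerance is 1e−8 on
imaginary parts; envelope boundary accuracy is at root-solver precision.

## Known limitations

* Five reefs give five support points per metric; envelopes and optima are
  quantized by the split midpoints between them, and extrapolation beyond
  the observed metric range is undefined by construction.
* Influence leakage to correlated metrics attenuates partial-dependence
  amplitude; the stump default mitigates but cannot remove it.
* The juvenile percent-survival convention counts censored individuals in
  the denominator; under heavy censoring prefer the Kaplan–Meier curve.
* The linear experiment heat-dose convention is not comparable to
  satellite DHW near the MMM, where the 1 °C gate matters.
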