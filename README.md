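# coralsource

Forecasting which reefs are likely to harbour corals whose offspring inherit
high heat tolerance — from sea-surface-temperature records and selective
breeding survival data.

Mass bleaching is driven by summer thermal anomalies, and heat tolerance in
corals is partly heritable: offspring of parents from some reefs survive
experimental heat stress far better than others. If the thermal regime of a
reef predicts the heat-stress survival of offspring bred from its corals,
then reef-scale temperature products can be used to nominate source reefs
for conservation and assisted-breeding programs without surveying every
reef. `coralsource` implements that forecasting chain for researchers
working on coral thermal adaptation and reef restoration planning:

1. **Thermal-regime metrics** (`coralsource.metrics`) — seven predictors per
   reef from daily/weekly SST series: latitude (LAT, °S), mean SST over a
   pre-bleaching window (`SST_av.pre`) and a longer window including
   bleaching years (`SST_av.post`), the standard deviation of daily SST
   (`SST_stdev`), mean daily temperature range (`DTR`), the year-to-year
   dispersion of SST-anomaly frequency (`SSTA_Freq_stdev`), and the
   dispersion of accumulated thermal-stress anomalies in degree heating
   weeks (`TSA_DHW_stdev`). Anomaly conventions are NOAA-style: MMM
   baseline, trailing 12-week accumulation, 1 °C counting thresholds — all
   configurable.
2. **Survival summaries** (`coralsource.survival`) — per-well larval percent
   survival, individual juvenile survival with the product-limit
   (Kaplan–Meier) bookkeeping and its n.event/(n.event + n.censor)
   percentage convention, pairwise two-sided Wilcoxon rank-sum tests with
   Bonferroni adjustment, and the implied thermal-tolerance boost
   (°C and DHW above the expected summer maximum) of heat-surviving groups.
3. **Boosted survival model** (`coralsource.boosting`) — stochastic
   gradient-boosted regression trees regressing offspring survival under
   heat on the *maternal* reef's seven metrics. statsmodels-style API:
   `BoostedSurvival(endog, exog).fit(GBMParams(...))` returns a results
   object with predictions, relative influence (share of squared-error
   reduction per predictor, summing to 100 %), partial dependence, k-fold /
   repeated k-fold / bootstrap / leave-one-out cross-validation, grid-search
   tuning, and leave-one-reef-out validation.
4. **Intrinsic-resistance equations** (`coralsource.resistance`) — the
   partial-dependence curve of a top predictor is reduced to a degree 3–5
   polynomial p(x); solving p(x) ≥ 90 (survival percent) inside the
   observed feature range yields the *environmental envelope* of high
   heat-stress survival, and the polynomial's maximum gives the survival
   optimum and its environmental value.
5. **Reef selection** (`coralsource.selection`) — a reef catalogue is
   classified against one or more envelopes; reefs whose metric values fall
   inside are predicted sources of heat-tolerant brood stock.

A first-class synthetic-data module (`coralsource.synthetic`) emulates the
whole study system — five source reefs with distinct thermal regimes, the
5 × 5 = 25 egg × sperm cross design, 20-larvae net-wells, individually
scored juveniles across four symbiont treatments in 24 tanks — with a known
smooth survival response to one driver metric, so every stage can be tested
against planted ground truth.

## Worked example

```python
import coralsource as cs

env = cs.default_reef_profiles()                      # 5 reefs × 7 metrics
design = cs.gen_cross_design(env["reef_id"].tolist()) # 25 crosses
table = cs.gen_survival(design, env, cs.default_true_response(), seed=1,
                        stages=("larva",))

model = cs.BoostedSurvival.from_survival_table(table, env, stage="larva")
res = model.fit(cs.GBMParams(n_trees=2500, interaction_depth=1,
                             bag_fraction=0.8, seed=3))
print(res.relative_influence().round(1).sort_values(ascending=False).head(3))
curve = res.partial_dependence("TSA_DHW_stdev")
ir = cs.IntrinsicResistance(curve, threshold=90.0).fit()
print(ir.summary())
```

Output from this exact run:

```
TSA_DHW_stdev    87.6
LAT              10.7
SST_av.pre        1.8
dtype: float64
Intrinsic resistance model — TSA_DHW_stdev
======================================================
Polynomial degree:   4
p(x) = -18.597 + 374.084·x^1 + -460.099·x^2 + 252.499·x^3 + -52.9381·x^4
Fit R2 on PD grid:   0.8048
Optimum:             94.95% at TSA_DHW_stdev = 0.9911
Envelope (>= 90%): [0.6485, 1.575]
```

The driver metric planted by the generator (`TSA_DHW_stdev`, with true
survival peaking at 1.2 °C-weeks and a true ≥90 % band of 0.78–1.62) takes
87.6 % of the influence; the fitted polynomial recovers an envelope of
0.65–1.58 °C-weeks overlapping the true band. Feeding that envelope to
`cs.classify_reefs(catalogue, [ir])` returns the reefs predicted to source
heat-tolerant offspring, with counts and fractions.

A command-line interface mirrors the stages
(`coralsource synth|metrics|survival|brt|ir|select`); run
`coralsource --help` for details.

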