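# hdallom

Local tree height–diameter allometries for forest biomass estimation:
how many height measurements are enough, and which trees should get
them?

Stand above-ground biomass (AGB) in tropical inventory plots is
computed from the allometry `AGB = 0.0673(ρD²H)^0.976` (ρ wood density
g/cm³, D diameter cm, H height m), so tree height matters — but
heights are slow to measure, and most plots rely on generic regional
or climate-based height–diameter (H–D) models instead. `hdallom` is a
toolkit for forest ecologists and inventory teams to quantify, by
cross-validation on plot data (or on synthetic stands with known
structure), the value of measuring heights locally:

* fit local H–D models — Weibull `H = a(1 − e^{−bD^c})`,
  Michaelis–Menten `H = aD/(b+D)` (each optionally with stem-volume
  case weights `w ∝ D²H`) and the log–log power law `ln H = a + b ln D`
  — from small field samples, by Levenberg–Marquardt / OLS;
* compare them against a regional Weibull reference and the
  pan-tropical climate model
  `ln H = 0.893 − E + 0.760 ln D − 0.0340 (ln D)²`;
* propagate height prediction error to stand-level AGB error;
* evaluate five field strategies for choosing the measured trees
  (random, size-class stratified, the n largest, and the 10 largest
  plus a random or stratified remainder);
* locate the diminishing-returns turning point of error versus sample
  size via the peak of the discrete second derivative
  `(I[n+2] − 2I[n] + I[n−2])/4` of a GCV-penalised spline trend.

See `docs/methods.md` for the models, experiment designs, the
synthetic stand generator and its limits.

## Worked example

Simulate six plots, cross-validate all models over training sizes
10–100, and locate the turning point:

```bash
hdallom simulate --n-plots 6 --seed 11 --out plots.csv --truth-out truth.csv
hdallom evaluate-size --input plots.csv --iterations 5 --seed 11 --output records.csv
hdallom thresholds --records records.csv --model weibull --model michaelis_menten \
    --output thresholds.csv
```

which prints `weibull: turning point at n = 40` (likewise
Michaelis–Menten), and the records give mean height RMSE (m) by
training sample size:

```
n_train            10    20    30    40    50    60    70    80    90    100
weibull           3.07  2.75  2.65  2.55  2.53  2.62  2.65  2.45  2.39  2.47
michaelis_menten  2.71  2.34  2.43  2.29  2.38  2.46  2.42  2.31  2.32  2.34
loglog            2.83  2.41  2.59  2.39  2.45  2.58  2.50  2.40  2.49  2.41
regional          5.09  4.98  5.13  4.96  5.03  5.11  5.12  5.06  4.97  5.11
climate           4.70  4.55  4.77  4.54  4.70  4.72  4.69  4.68  4.58  4.72
```

Read: with as few as 10 locally measured heights, every local model
form predicts held-out tree heights roughly twice as accurately as the
pooled regional or climate references (≈ 2.7–3.1 m vs ≈ 4.5–5.1 m
RMSE), errors shrink with more measurements, and the improvement
flattens near 40 trees — the turning point. The same records CSV
contains stand-AGB errors per cell, and `hdallom evaluate-strategy`
produces the analogous table across sampling strategies.

The library API mirrors the CLI (`hdallom.fit_hd_model`,
`run_size_experiment`, `run_strategy_experiment`, `best_tally`,
`mean_difference_ci`, `find_threshold`, `generate_dataset`, …) and
returns tidy pandas DataFrames.

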