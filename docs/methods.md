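# Methods

## The problem

Stand-level above-ground biomass (AGB) in tropical forest inventory is
estimated from allometric equations driven by trunk diameter, wood
density and total tree height. Measuring every tree's height is
impractical, so heights are usually predicted from diameter with a
height–diameter (H–D) allometry. This package quantifies, on synthetic
stands with known structure, how many local height measurements are
needed before a locally fitted H–D model beats generic reference
allometries, how height errors propagate to stand AGB, and which field
strategy for choosing the measured trees works best.

## Models

Three local model forms relate height H (m) to diameter D (cm):

* **Weibull** `H = a(1 − exp(−b·D^c))` — `a` is the asymptotic maximum
  height (m); `b`, `c` shape the approach to it.
* **Michaelis–Menten** `H = aD/(b + D)` — `a` the asymptote (m), `b`
  (cm) the diameter at half the asymptote.
* **log–log power law** `ln H = a + b ln D` — `b` the scaling exponent;
  unbounded in D.

The two nonlinear forms are fitted by Levenberg–Marquardt with analytic
Jacobians; starting values are `a₀ = 1.1 × max(H)`, `b₀ = 0.03`,
`c₀ = 1` for the Weibull and a Lineweaver–Burk linearisation for
Michaelis–Menten, with up to five log-normally jittered restarts before
a fit is recorded as non-convergent. Non-convergence is a recorded
outcome, never an exception, so downstream tallies can count failures
as losses. Optional case weights `wᵢ ∝ Dᵢ²Hᵢ` (a stem-volume proxy,
normalised to mean 1) emphasise the large trees that dominate stand
biomass; `D²` alone would be a defensible alternative, but the observed
training height is available at fit time and carries real information
about volume. The log–log form is ordinary least squares on
`(ln D, ln H)`; predictions are back-transformed with the standard
correction factor `exp(s²/2)` (s = ln-scale residual SE), on by
default and switchable off, since the naive back-transform estimates
the median rather than the mean height.

Two reference allometries represent the no-local-data situation: a
regional Weibull with fixed externally supplied parameters (for
synthetic experiments, a Weibull pooled over all plots — a faithful
stand-in for a coarse-scale allometry that ignores plot-to-plot
variation), and the pan-tropical climate-based model
`ln H = 0.893 − E + 0.760 ln D − 0.0340 (ln D)²`, where the bioclimatic
stress scalar `E = (0.178·T − 0.938·C − 6.61·P)×10⁻³` is a per-plot
input (T temperature seasonality, C climatological water deficit, P
precipitation seasonality).

Tree AGB uses the diameter–height–density allometry
`AGB (kg) = 0.0673(ρD²H)^0.976` with ρ in g/cm³. Stand-level AGB error
of a height model is the summed AGB of the test trees with predicted
heights minus the sum with observed heights; the allometry's own error
is deliberately outside scope, as both sums share it.

## Experiments

**Inclusion filters.** A height enters fitting only if the stem is not
broken or fallen, leans < 10 %, the height is < 90 m (taller records
are treated as blunders), and the instrument is a clinometer, laser
rangefinder, laser hypsometer or direct climb. Plots qualify with
≥ 150 usable heights, so a 100-tree training draw plus a 50-tree test
draw always fits.

**Size experiment.** Per plot, training size n ∈ {10,…,100 step 10} and
iteration: draw a random n-tree training set and a disjoint 50-tree
test set, fit all five local variants, score them and the two fixed
references on the same test trees (height RMSE; stand-AGB error). Both
draws are fresh each iteration.

**Strategy experiment.** Five field strategies pick the n training
trees: Rand (simple random), Strat (random within diameter classes
< 200, 200–300, 300–500, ≥ 500 mm, allocated by largest-remainder
proportionality), Big (the n largest), BigRand and BigStrat (the 10
largest plus a random / stratified remainder drawn from the remaining
trees, with strata proportions over those remaining trees). Because
Big-type strategies deplete parts of the diameter distribution, models
are scored on *all* height-measured trees of the plot, and a cell's
score is the better of the Weibull and Michaelis–Menten fits.

**Summaries.** The winner of a cell (plot × size × iteration) is the
competitor with the smallest criterion; non-converged fits cannot win
and exact ties are broken uniformly at random with a cell-derived seed
(so tied competitors split cells evenly in expectation, and reruns are
bit-identical). Probabilities of being best, and paired mean RMSE
differences, carry 95 % intervals from a cluster bootstrap that
resamples plots — cells within a plot share trees and are not
independent. This replaces mixed-effects/GLMM machinery while keeping
the same estimands; run manifests record the substitution.

**Turning point.** The mean-RMSE-versus-n series is smoothed with a
low-rank penalised natural cubic regression spline: 4 basis functions
(knots at evenly spaced quantiles of the observed sizes), an exact
integrated-squared-curvature penalty, and the penalty weight chosen by
generalised cross-validation. The smoother reproduces any linear trend
exactly at every smoothing level (linear functions span the penalty
nullspace) — the key correctness oracle. The fitted trend is evaluated
on the unit-spaced integer grid and differenced as
`d2(n) = (I[n+2] − 2I[n] + I[n−2])/4`, exact for cubics; the turning
point is the interior argmax, ties toward smaller n, with the whole
series returned because the location is sensitive to the degree of
smoothing and should be inspected, not consumed blindly. A spline with
interior knots (rather than a single global cubic) matters here: for a
convex decreasing trend its piecewise-linear second derivative peaks at
an interior knot, which is what makes an interior turning point
detectable at all.

## Synthetic stands

Each plot draws 200–600 stems with diameters `10 + Exp(mean 12) cm`
truncated at 250 cm (a reverse-J size distribution), a plot-specific
true allometry drawn from *both* asymptotic families (50:50 Weibull
with a ~ U(25,50) m, b ~ U(0.02,0.08), c ~ U(0.7,1.1); Michaelis–Menten
with a ~ U(30,60) m, b ~ U(15,40) cm) so model-form comparisons are not
rigged, observed heights `H·exp(ε)`, ε ~ N(0, 0.13²), floored at 1.5 m
(multiplicative noise keeps heights positive and makes absolute error
grow with tree size, as height measurement error does; σ = 0.13 puts
the residual RMSE of a well-fit local model near 4 m on tall stands),
wood densities from N(0.60, 0.10²) g/cm³ truncated to [0.25, 0.95], a
per-plot climate scalar E ~ U(−0.1, 0.1), and 1 % defective stems
(broken / leaning ≥ 10 % / fallen / heights ≥ 90 m) to exercise the
filters. True parameters go to a separate truth manifest so pipeline
code cannot read them. Per-plot seeds spawn deterministically from one
master seed.

What the generator does **not** emulate: species identity, spatial or
topographic structure, directional instrument bias, diameter
measurement error, and any correlation between wood density and
allometry. Passing tests therefore demonstrate the statistical
machinery under the stated noise model, not performance on any real
forest.

## Default problem sizes

The end-to-end checks run 30 plots × 10 sizes × 25 iterations for the
size experiment, the strategy experiment at n = 50, and ten replicate
datasets (10 iterations, Weibull only) for turning-point stability —
enough that per-size means rest on ≥ 300 cells while a full run stays
in the minutes range on one core. The CLI runs any sizes/iterations.

## Numerical choices and edge cases

* Diameters are stored in cm; loader dialects declare mm inputs, and
  the mm strata thresholds are converted (200 mm = 20 cm).
* Largest-remainder allocation resolves proportionality exactly when
  divisible and deterministically otherwise (remainder ties to the
  smaller size class); allocations are capped at class counts with
  excess reallocated by the same rule.
* Diameter ties in "largest tree" selection break by canonical row
  order (input row order within a plot), making every draw
  reproducible.
* GCV searches λ on a 62-point log grid including 0; a degenerate
  (edf ≈ points) fit is skipped rather than divided by ~0.
* All experiment randomness derives from `SeedSequence(master_seed,
  spawn_key=...)`; two runs with one seed write byte-identical CSVs.
* Wood density resolution: tree value, else plot mean, else 0.6 g/cm³.

## Known limitations

* Small training samples from reverse-J stands contain few large
  trees, so the asymptote is weakly identified: the fitted Weibull a
  is near-unbiased in median but heavily right-skewed, with a tail of
  effectively unsaturating (power-law-like) solutions along the
  a→∞, b→0 ridge. Optimiser termination interacts with this ridge —
  stopping LM early systematically attenuates a and induces a
  negative stand-AGB bias of order 1 %, which is why the evaluation
  budget is generous (2000 function evaluations) before a fit is
  declared failed. Residual stand-AGB biases of the asymptotic forms
  are below ~0.5 % and statistically indistinguishable from zero at
  the plot-cluster level, while the uncorrected log–log form
  overestimates by ~3 %.
* The pooled-Weibull "regional" reference is only a stand-in; with
  real regional parameter sets the reference gap will differ.
* The turning point is a property of the smoothed trend; with other
  basis dimensions or smoothing penalties its location can move by
  tens of trees. Inspect the second-derivative series.
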