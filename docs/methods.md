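# Methods

## The calibration problem

Vis-NIR reflectance calibration relates a matrix of berry reflectance
spectra **X** (samples × wavelengths) to a chemical reference variable
*y* (SSC in %, TA in g/L tartaric-acid equivalents, or pH). The
workflow implemented here — pretreatment, rank-based sample splitting,
characteristic-wavelength selection, regression, RPD-based evaluation —
is the standard design of fruit-quality calibration studies. All
stateful estimation (MSC reference, standardization constants, selector
decisions, hyperparameters) uses calibration rows only; prediction rows
are seen exactly once, at evaluation time.

## Synthetic storage trial

Real spectra for this kind of trial are rarely published, so the package
ships a generative stand-in (`synthetic_data`) whose defaults emulate a
145-berry trial: 15 days of storage at 2.7 °C, 10.0 °C and 20.6 °C,
sampled every third day, with samples assigned round-robin to the
(temperature, day) cells.

**References.** Each parameter is drawn from a truncated normal with the
trial's descriptive statistics — SSC ∈ [9.23, 22.73] % (mean 17.35, sd
2.30), TA ∈ [3.87, 9.79] g/L (5.92, 1.46), pH ∈ [3.06, 4.59] (3.82,
0.20) — plus a monotone storage drift that grows linearly with day and
temperature: zero at the coldest condition and
`storage_trend_fraction` (default 0.10, i.e. ±10 % of the parameter
mean) at the warmest condition on the final day. SSC and pH drift up,
TA down, so reference values correlate with storage metadata as they
would in a senescing fruit. The drift magnitude is a free parameter: it
produces a realistic spread without asserting any ripening kinetics,
which the generator deliberately does not model. Values are clipped
back into the configured range after the drift, and the drift is a
*separate* config field, so a degenerate sd → 0 configuration with the
drift disabled collapses exactly to the configured mean.

**Spectra.** Each spectrum is

```
R(λ) = gain · [ B(λ) + baseline(λ) + Σ_b c_b · y_{p(b)} · G(λ; λ_b, w_b) ] + offset + ε(λ)
```

where *B* is a fixed background (yellow-green skin peak around
530–630 nm, peaks at 720 and 810 nm, a chlorophyll valley at 670 nm and
a water/carbohydrate valley at 970 nm), *G* is a unit-height Gaussian,
gain ~ U(0.9, 1.1), offset ~ N(0, 0.01), ε ~ N(0, 0.003) per point, and
reflectance is clipped into (0, 1] (defaults chosen so clipping never
engages in practice). The planted bands are:

| parameter | bands (center nm, width nm, coefficient) | per-channel signal sd |
|-----------|------------------------------------------|-----------------------|
| SSC | (970, 12, −0.004), (840, 10, +0.003) | ≈ 0.009 / 0.007 |
| TA  | (890, 10, −0.008), (1040, 12, +0.006) | ≈ 0.012 / 0.009 |
| pH  | (1010, 35, +0.004) | ≈ 0.0008 |

SSC and TA bands sit well above the 0.003 noise floor; the pH band sits
below it and is broad, making pH deliberately the hardest target. This
mirrors the physical situation: sugar and acid concentrations have
direct O–H/C–H overtone signatures, while pH is an activity, not a
concentration, and couples to spectra only indirectly. Indices within
±1 band width of each planted center are recorded as ground truth.

One seed governs the dataset; per-sample (and per-replicate) RNG
substreams are derived from it, so output is bit-reproducible and
independent of generation order. Replicate scans (`n_replicates`) share
the clean spectrum and redraw gain, offset and noise, emulating probe
repositioning; `average_replicates` then reduces noise variance by the
replicate count.

**What the generator does not emulate.** Biochemical kinetics,
skin/flesh/seed structure, instrument line-shape, wavelength-dependent
noise, dark/white-reference drift and non-uniform pixel grids. Passing
tests therefore demonstrate correctness of the algorithms and their
relative behaviour under known structure — not performance claims for
any real instrument or cultivar.

## Preprocessing

* **FD** is a grid-aware central difference (one-sided at the ends),
  dividing by Δλ (units 1/nm); it is deliberately *not* implemented as a
  Savitzky–Golay derivative because FD, S-G and FD+S-G are three
  distinct treatments in the evaluated set.
* **S-G** uses least-squares polynomial convolution (scipy), default
  window 11 points, polynomial order 2 — conventional chemometric
  defaults, exposed in config. Endpoints use the one-sided polynomial
  fit.
* **SNV** centers and scales each spectrum (n−1 denominator); a
  zero-variance spectrum is an error naming the sample.
* **MSC** regresses each spectrum on the calibration-mean reference and
  returns (x − b0)/b1; the reference is frozen at fit time so prediction
  spectra never influence it. |b1| < 1e−10 is an error naming the
  sample.

The evaluated pretreatment set is {raw, FD, S-G, FD+S-G, MSC, SNV},
applied left-to-right as listed in the chain spec.

## Gradient concentration split

Samples are sorted by reference value (stable sort, ties by input
order) and walked in blocks of 4 (for 3:1); the 2nd-ranked member of
each complete block goes to prediction, everything else — including the
n mod 4 leftovers — to calibration. Choosing block position 2 (rather
than 1 or 4) keeps both extremes in calibration, which guarantees the
range-coverage property these studies verify, and yields 109/36 from
145 samples. Splits are per-parameter by default (each parameter
ordered by its own values); a shared split is available via
`per_parameter_split=False`.

## Wavelength selection

**SPA.** Chains are grown from every nonzero-norm starting column by
successive orthogonal projection (vectorised over batches of starts);
each chain prefix of size 1..`max_vars` (default 30) is scored by MLR
RMSE on an internal 3:1 rank split of the calibration rows, evaluated
cheaply through a single QR factorisation per chain with nested
triangular solves. Rank-deficient prefixes score +∞.

**UVE.** A uniform [0, 1e−10·max|X|] noise matrix of equal width is
appended; leave-one-out PLS (default 10 latent variables) yields
per-fold coefficient vectors; stability is t = mean/sd across folds
(sd = 0 maps to ±∞ with a warning). The cutoff is 0.99 × max |t| over
the noise columns. Because that extremal cutoff grows with the number
of noise columns, a weak-signal target can lose *every* real variable;
in that degenerate case the two most stable real variables are retained
with a warning so a (deliberately minimal) model can still be built.
`min_keep=0` disables the fallback and exposes the raw elimination
rule.

**CARS.** Default 100 Monte-Carlo runs, each fitting PLS on a random
80 % row subset of the retained variables. The enforced retained
fraction is r_i = a·e^(−k·i) with k = ln(p/2)/(n_runs − 1), a = e^k, so
r_1 = 1 and r_{n_runs} = 2/p; after the enforced top-|b| cut the
surviving set is drawn by weighted sampling with replacement
(survivors = unique draws), clamped at ≥ 2 variables. Each run records
5-fold RMSECV of a PLS model on the survivors; the minimal-RMSECV run
defines the selection. Retained counts are non-increasing by
construction. Seeds are mandatory; there is no hidden global RNG.

## Regression

**PLSR** is NIPALS PLS1, column-centered only (no scaling), with the
latent-variable count chosen by 5-fold cross-validated RMSE over
1..20 (capped by data size). The CV exploits NIPALS nesting: one
decomposition per fold yields all sub-models. **SVR** is ε-SVR with RBF
kernel (scikit-learn's libsvm core); c and g are grid-searched over
2⁻⁸..2⁸ (17 log-spaced points each) by 5-fold RMSECV with deterministic
interleaved folds, ε defaults to 0.01·sd(y), inputs are standardized by
calibration statistics, ties go to the first candidate in grid order.
**ELM** draws input weights and biases uniform [−1, 1] from a seeded
generator, applies a sigmoid hidden layer (default 50 neurons) and
solves the output weights by Moore–Penrose pseudo-inverse; inputs are
standardized. An identity-activation variant exists mainly to make the
linear-span behaviour testable against OLS.

A `FittedModel` can carry its frozen preprocessing chain and wavelength
subset, and `predict` then replays preprocessing → subset →
standardization → model on full-grid spectra with no refitting.

## Evaluation

Rc/Rp are Pearson correlations (an R² column is also emitted, since the
literature uses "correlation coefficient" and "coefficient of
determination" interchangeably for values in this range); RMSE uses the
n denominator; RPD divides the prediction-set reference sd (n−1
denominator) by RMSEP — this combination satisfies
RPD·RMSEP = sd(prediction y) exactly, which the tests assert to 1e−10.
A constant predictor is assigned R = 0 rather than NaN. The grid runner
derives one deterministic seed per cell from the config seed, so
reports are bit-identical across reruns.

## Numerical choices and degenerate inputs

* NIPALS stops extracting components when residual covariance vanishes
  (unit-free tolerance 1e−13); a fully degenerate fit returns the mean
  predictor with zero coefficients.
* SPA treats projected squared norms below 1e−12 of the largest initial
  norm as exhausted and terminates the chain.
* CARS clamps the survivor set at 2 variables; zero total |coefficient|
  falls back to uniform resampling weights.
* Constant y: error for PLSR and the selectors (undefined objective);
  constant predictor with a warning for SVR.
* Reported problem sizes: the default simulation is the full 145 × 1401
  trial; the unit-test fixtures use a reduced 60 × 201 grid
  (700–1100 nm at 2 nm) that keeps every planted band on-grid, chosen so
  the whole suite exercises identical code paths at interactive speed.

## Known limitations

* The generator's linear band model makes SNV/MSC near-exact
  corrections; real scatter is wavelength-dependent and only
  approximately multiplicative.
* SPA scans every starting column; on very wide grids (≫ 2000 columns)
  the batched projection phase dominates runtime.
* UVE's leave-one-out coefficient spread underestimates true
  variability (folds share n−2 rows), inflating all t values; the noise
  columns calibrate this inflation, which is exactly why the extremal
  cutoff can be aggressive on weak signals.
* The ELM is intentionally minimal (no regularisation); with many
  selected variables it overfits, which is visible — and expected — in
  the grid reports.
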