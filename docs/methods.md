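# Methods

## Model and assumptions

`lemsurv` treats clonogenic survival through the local effect model (LEM)
reading of the linear-quadratic (LQ) response.  Cell inactivation is
attributed to lethal lesions (local DNA damage, e.g. double-strand breaks)
created in a sensitive sub-cellular volume; lesion counts are Poisson, so

    SF(D) = exp(−⟨N(D)⟩),   ⟨N(D)⟩ = αD + βD²  with α, β ≥ 0.

For a cell population doped with high-Z nanoparticles at concentration `C`,
the total lesion count splits into a bulk-cell part and a
nanoparticle-generated part.  Two assumptions make the concentration
dependence tractable:

1. **Negligible cross term.**  The probability of a bulk-dose and a
   nanoparticle-dose deposit at the same location is negligible over the
   LQ validity range, so the lesion counts add.
2. **Linear density scaling.**  If the spatial pattern of nanoparticle
   uptake is approximately concentration-independent, nanoparticle lesions
   scale with average nanoparticle density up to a saturation threshold:
   `⟨N_NP(C,D)⟩ = (C/C₀)(⟨N_total(C₀,D)⟩ − ⟨N_U(D)⟩)`.

The spatial dose integrals implied by assumption 1 never need to be
evaluated: they cancel into the fitted endpoint coefficients, so the
interpolated response is again LQ with coefficients affine in `C/C₀`.
Consequences used as invariants throughout the test suite:

* `ln SF(C,D)` is affine in `C` at fixed `D` (geometric interpolation of
  the endpoint curves);
* the endpoints are reproduced exactly at `C = 0` and `C = C₀`
  (implemented bitwise: the boundary returns the endpoint parameter
  objects themselves);
* when both endpoint differences Δα, Δβ are non-negative — true for all
  bundled benchmark pairs — interpolated curves lie pointwise between the
  endpoint curves and survival is monotone non-increasing in both `C` and
  `D`.

**Domain restrictions.**  Concentrations outside `[0, C₀]` are rejected by
default; no numeric saturation threshold is available, so an explicit
`allow_extrapolation` flag permits evaluation with a warning.  An
interpolated coefficient can only go negative under extrapolation with a
"protective" endpoint pair (Δ < 0); it is then clamped to zero with a
warning, mirroring the positivity restriction of the fits.  Doses outside
the quoted 1–6 Gy LQ validity range warn but evaluate (0 Gy controls are
routine).  The survival domain is `(0, 1]` in the maths layer; measured
*means* slightly above 1 (a normalisation artefact) are tolerated by the
fitting layer.

## Fitting protocol

Endpoint parameters are estimated exactly the way published survival-curve
tables are produced: least-squares regression with α and β restricted to
non-negative values.

* **Fit space.**  Default is log-survival, where the model is linear and
  the restriction makes the problem non-negative least squares
  (`scipy.optimize.nnls`); an alternative `"sf"` space minimises residuals
  on the survival scale with box constraints
  (`scipy.optimize.least_squares`, initialised from the log fit).  The two
  differ only in how noise is weighted across the dose range.
* **No intercept.**  `SF(0) = 1` by construction; the 0 Gy control
  contributes a zero design row and is excluded from the regression (tests
  confirm including it does not move the optimum).
* **Weighting.**  Unweighted by default; optional inverse-variance weights
  with the delta-method map into log space, `var(ln SF) ≈ sd²/SF²`
  (variances floored at 1e-12 so zero-sd points cannot produce infinite
  weights).
* **Means above 1** are retained (their log is negative and the constraint
  handles them); clipping would silently bias α downward.  Non-positive
  means are rejected, or dropped with a warning on request.
* **Active constraints** are flagged via the KKT conditions (coefficient
  at zero with a strictly positive objective gradient), so an exactly-zero
  noiseless coefficient is not spuriously marked "clamped".

### Parameter uncertainty

Two routes, labelled explicitly in all outputs because published ± values
rarely state their convention:

* **analytic** — the linear-model covariance `σ̂²(XᵀX)⁻¹` in the fitting
  space.  Reported as *absent* (not zero) when a positivity constraint is
  active, where the quadratic approximation fails.
* **bootstrap** (default) — residual-resampling with `b` refits under the
  same constraints; standard errors are the bootstrap standard deviations.
  Residuals are leverage-adjusted (`r/√(1−h)`), centred, and rescaled by
  `√(n/(n−1))`: with only ~5 design points, raw residuals understate the
  noise level substantially (mean leverage 2/5).

  Confidence intervals are **studentised** (bootstrap-t).  Percentile
  intervals at n ≈ 5 behave like a normal interval whose scale estimate has
  ~3 degrees of freedom and undercover badly (≈0.86 true coverage at the
  nominal 95 %).  The studentised pivot is built from the *unconstrained*
  linear refits: clamping the resampled estimates would truncate the
  pivot's tails whenever the estimate sits within a few standard errors of
  the boundary, cutting the upper bound exactly in the studies that need
  it (observed as 0.87 vs 0.94 coverage before/after this choice).  The
  final interval is intersected with the non-negative parameter space.
  Every stochastic path takes an explicit seed; there is no hidden global
  state.

Near the positivity boundary the *point estimator* is biased upward by
construction — a truth of α = 0 can only be over-estimated.  That is the
intended behaviour of the restriction, not a defect; estimator-calibration
studies (unbiasedness within Monte-Carlo error, interval coverage) are
therefore run with interior ground truth (α_U = 0.05 Gy⁻¹, β_U = 0.01 Gy⁻²,
doped α = 0.08 Gy⁻¹, β = 0.02 Gy⁻², i.e. α/β of 5 and 4 Gy — typical
radiobiology magnitudes, all ≥ 2.6 estimator-SDs from the boundary).

An internal closed-form two-parameter NNLS (`_nnls2_batch`, exact for
p = 2 by enumerating the three candidate active sets) vectorises the
bootstrap refits; it is tested against `scipy.optimize.nnls` to 1e-9.

## Diagnostics

* **Percent difference**: `100·(observed − fitted)/fitted` per point
  (positive = measurement above the fitted curve; the convention is stated
  in output headers because the quantity is often plotted without one).
  Positive-dose points by default; fitted values that underflow to zero
  are flagged and excluded from the |%| summaries.
* **Coverage counting**: a prediction covers a measurement when
  `|SF_pred − SF_mean| ≤ k·sd`, default `k = 1` (error bars are ± one
  cell-survival standard deviation).  Exact dose alignment is required —
  predictions are generated on the measured grid, never interpolated
  across dose.  Predicted-curve uncertainty bands are deliberately *not*
  included in the tolerance; only the measurement scatter counts.
* **Prediction workflow**: pairs fitted endpoints per spectrum
  (concentration 0 = undoped, highest concentration = reference;
  intermediate doped fits are ignored since the interpolation is defined
  by its endpoints) and evaluates predictions over `(concentration, dose
  grid)` targets, sorted by spectrum so output is independent of input
  order.

## Synthetic-data generator

The generator emulates the benchmark study design: three kilovoltage
spectra (80/100/150 kVp), four concentrations (0, 0.25, 0.5, 1.0 mMol/L),
each curve a 0 Gy control plus five dose irradiations in triplicate, with
the interpolated LQ response as the noiseless mean.  Defaults chosen once:

* **Dose grid 0, 1, 2, 3, 4, 5 Gy** — the source study does not print its
  dose levels; five 1 Gy steps inside the 1–6 Gy LQ validity range are a
  realistic superficial-therapy escalation.
* **Noise σ = 0.05, multiplicative** (`SF·(1+ε)`, ε ~ N(0, σ²), floored at
  1e-6 so log fits stay defined).  No numeric assay variance is published;
  5 % matches the visual scale of typical clonogenic error bars.  Whether
  real proliferation-assay noise is additive or multiplicative is not
  knowable from summary data; multiplicative is the shipped default.
* **Poisson colony mechanism** — an idealised clonogenic assay: each of
  `cells_plated` cells (default 1000) draws lesions ~ Poisson(αD + βD²)
  and founds a colony iff it draws none and an independent plating draw
  (default efficiency 0.8) succeeds; per-replicate counts are binomial
  with success `PE·exp(−λ)`, which is sampled directly.  Replicate SF is
  normalised to the same condition's mean control colony count (standard
  clonogenic practice; an `"expected"` mode divides by `cells·PE`
  instead), floored at half a colony.  The zero-lesion fraction converging
  to `exp(−αD−βD²)` ties the simulator mechanically to the survival model.
  The benchmark study actually used a proliferation assay as a survival
  surrogate — the colony mechanism is a deliberate idealisation.
* **Randomness**: one root seed with per-condition substreams keyed by
  (CRC32 of the spectrum label, concentration), so adding a spectrum or
  concentration never perturbs other conditions' draws, and identical
  inputs give byte-identical datasets.

What passing tests on this generator do *not* show about real data: real
assays have plating-density effects, inter-experiment drift, non-Gaussian
outliers and dose-delivery uncertainty, none of which are modelled; the
generator demonstrates correctness of the pipeline's mathematics and
statistics under its stated noise model, not assay realism.

## Numerical and design choices

* Boundary concentrations return the endpoint parameter objects, making
  endpoint reproduction exact by construction rather than to rounding.
* Prediction uncertainty bands are first-order delta-method propagation of
  endpoint standard errors through the interpolation, treating the two
  endpoint fits as independent (published tables report ± values but no
  covariance): `var(ln SF) = D²·var(α(C)) + D⁴·var(β(C))` with
  `var(α(C)) = (1−t)²·se_U² + t²·se_C0²`.
* Concentration units are opaque (mMol/L in the benchmark); only the ratio
  `C/C₀` enters the mathematics, so no unit-conversion layer exists.
* CSV numbers are written at `%.17g` and parsed with Python's `float`,
  making file round trips bit-exact (pandas' fast parser is not
  round-trip-safe and is deliberately bypassed).
* Problem sizes in the validation suite — 61-point dose grids, 21-point
  concentration grids, 100 oracle-checked random fits, 500 simulated
  recovery studies with 500 bootstrap refits each — keep the full suite
  and the acceptance script in the tens of seconds on one CPU while
  holding Monte-Carlo error well below the margins being tested.

## Known limitations

* The framework is an interpolation: it says nothing above `C₀` (saturation
  is real but its threshold is unknown) and inherits all input-fit error —
  noisy endpoint data propagate directly into predictions, which is why
  the within-uncertainty coverage diagnostic exists.
* Constrained estimates at the positivity boundary are biased upward and
  carry no analytic standard errors; bootstrap SEs there describe a
  truncated distribution.
* The delta-method prediction band ignores endpoint-fit covariance and is
  symmetric in lesion space, not survival space.
* The mechanistic simulator treats cells as independent with a single
  plating-efficiency parameter; colony-merging, feeder effects and
  abortive colonies are out of scope.
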