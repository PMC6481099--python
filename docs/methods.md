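# Methods

## Problem and approach

Single-use colorimetric assay packs (and test strips generally) turn an
analyte concentration — chemical oxygen demand, ammonium, phosphate — into a
color. Read against a discrete chart of standard colors, they are
semiquantitative at best; read from a scanned RGB image, the three digital
numbers per pixel carry more information than the eye extracts, but single
channels respond nonmonotonically to concentration and no one channel is a
usable calibration curve on its own.

The pipeline implemented here multiplies the information in one scan by
*pseudocolor channel substitution*. From the R, G and B component images,
three hybrid channels are built by equal-weight pixel merges
(yellow = (R+G)/2, cyan = (G+B)/2, magenta = (R+B)/2). Substituting hybrids
(plain or black-white inverted, v → 255 − v) into the slots of the RGB image
yields ten canonical pseudocolor images (`RGyB`, `RG-yB`, `RmGB`, `R-mGB`,
`cRGB`, `-cRGB`, `RmGyB`, `cRGyB`, `cRmGB`, `cRmGyB`). Each pseudocolor image
is re-separated into C, M, Y, K, L\*, a\*, b\*, giving 70 derived channels;
with the ten base channels (R, G, B, C, M, Y, K, L\*, a\*, b\*) and the three
hybrids, 83 grayscale channels per scan. These are deterministic, invertible
recombinations — no new measurement — but they hand a regression model a
large library of monotone-in-different-places transforms of the same three
signals, which is what makes small linear models competitive and gives the
network a well-conditioned input.

Per reacted pack, replication pixels (default 10 training + 5 validation)
are read across all channels; pixels from every standard-solution level and
pack form the training and validation tables of one study.

## Color separations

All channels are 8-bit digital numbers, 0 = black, 255 = white.

- **CMYK** uses the naive gray-component-replacement formula: with
  r′, g′, b′ ∈ [0, 1], K = 1 − max(r′, g′, b′) and
  C = (1 − r′ − K)/(1 − K) away from pure black (M, Y analogous), encoded as
  255·(1 − coverage). Commercial separations go through proprietary ICC
  profiles; the naive formula is chosen because it is platform-exact and
  fully specified. Absolute agreement with any particular ICC engine is not
  claimed and not needed: every model is trained and applied within one
  consistent separation convention.
- **L\*a\*b\*** assumes sRGB input: gamma expansion, the D65 sRGB matrix to
  XYZ, Bradford adaptation to D50 (the ICC profile-connection convention),
  then CIE L\*a\*b\* against the D50 white. Encoding matches common image
  editors: L\* scaled from [0, 100] to [0, 255]; a\*, b\* offset by +128 and
  clipped.
- Rounding is round-half-up throughout, fixed because exact .5 cases occur
  in equal-weight merges ((255 + 0)/2 → 128).

## Quantification models

**Five-stage network.** Four affine blocks with tanh activations (widths
64-64-32-16 by default) and one sigmoid output unit; mean squared error;
full-batch Adam (learning rate 1e-3, β₁ 0.9, β₂ 0.999) for 3000 epochs;
Glorot-uniform initialization from a fixed seed, so training is
bit-reproducible. Inputs are intensities divided by 255. Because the output
is a sigmoid, the concentration target is min-max mapped into [0.1, 0.9]
rather than [0, 1]; saturating the sigmoid at the extreme standards would
flatten gradients exactly where the calibration anchors are. Predictions
invert that affine map, so they can exceed the calibrated range slightly,
which is the desired behaviour for out-of-range warnings. A degenerate
single-level target pins the scaler and hence every prediction to that
level. Per-epoch training (and optional validation) loss is retained so
overtraining shows up as diverging curves; at these data sizes (≤ 400 × 83)
the two stay together.

With ~400 rows and 83 strongly dependent features the network's job is
interpolation over a three-dimensional manifold (everything is a function of
R, G, B); four hidden layers are more than enough capacity, and the fixed
seed plus full-batch updates remove run-to-run variance.

**Stepwise multiple regression.** Classical forward-backward selection on
partial-F p-values: enter the candidate with the smallest p ≤ 0.05, remove
any included predictor with p ≥ 0.10, iterate to a fixed point. The entry
scan residualizes all candidates against the current model in one orthogonal
projection — algebraically identical to the per-candidate t-test, just
vectorized — and refuses candidates whose tolerance (1 − R² on the included
set) falls below 1e-4, the classical guard against numerically collinear
entries; ties resolve to the earlier channel in registry order. After
convergence, variance inflation factors (1/(1 − R²) of each predictor on the
rest) are checked: a model containing any VIF ≥ 10 carries an unreliable
coefficient, so the worst offender is banned from the candidate pool and the
search restarts. The accepted model is refit by ordinary least squares
(statsmodels) and reported as a named-channel equation. The linear model
consumes raw 0–255 intensities, so published equations with named channels
apply directly.

**Range restriction.** When the zero-concentration reference pack produces a
false-positive estimate (typical for ammonium/phosphate chemistry, where the
blank still develops some color), the zero level can be excluded from
evaluation; the report then states the effective measurable range as
[lowest remaining level, highest level].

## Evaluation statistics

- NMAE% = 100 · mean|estimated − actual| / range of value. The range
  defaults to max − min of the actuals but should be the full design range
  when levels were excluded.
- CV% = 100 · sd/mean with the sample (n−1) standard deviation, used for
  scanner repeatability.
- Estimated-vs-actual: OLS of estimates on actuals; slope 1, intercept 0,
  R² 1 is a perfect match. The report carries both this R² and the model-fit
  R² where applicable, since summaries in the field do not always
  distinguish them.
- PCA profile: z-scored columns, eigendecomposition of the correlation
  matrix (its eigenvalues sum to the variable count, which is also how one
  recognizes the convention in published tables), loadings =
  eigenvector · √eigenvalue, Kaiser retention (eigenvalue > 1), no rotation.
  Constant columns are dropped with a warning. On synthetic studies the 83
  channels collapse to a handful of retained components, as expected for
  deterministic recombinations of three base signals.

## Synthetic studies

The simulator exists so every stage is testable end to end without the
original scans, which are not deposited.

- **Response curves** are defined at the R, G, B level only; all 83 channels
  inherit structure through the real pipeline. R falls and B rises with
  concentration, each a linear trend plus a saturating term (the saturating
  component keeps the closely spaced low standards resolvable, the linear
  component keeps sensitivity at the top of the range); G carries a Gaussian
  bump that guarantees an interior extremum — a nonmonotonic channel —
  within the calibrated range, as observed for real pack colorations. Curve
  parameters are jittered ±8% by the seed around these templates.
- **Noise.** One multiplicative gain per pack with CV 3% (default) models
  pack-to-glass attachment and scan-to-scan differences, which act chiefly
  as a common brightness change; 3% is the scale of scanner repeatability
  measured on printed reference colors. Independent multiplicative
  per-pixel-per-channel noise with CV 0.5% (default) models within-pack
  texture; it is set well below the between-pack CV because replication
  pixels are deliberately taken from the most uniform image region. The
  within-pack figure is an assumption (no published value exists) and is
  tunable. Quantization to 8 bits happens after noise, as in a scanner.
- **Pixel selection** in simulated studies uses the same low-variance rule
  as real images: rank ROI pixels by 3×3 local variance summed over base
  channels, take the least-variable ones with seeded tie-breaking, alternate
  ranks between train and validation. This is a reproducible surrogate for
  the manual "least diffuse reflection" criterion; explicit coordinates
  remain available as the escape hatch.
- Validation pixels share their pack with training pixels (the within-pack
  split used in the original studies), so validation error is bounded below
  by within-pack noise, not by generalization to unseen packs. An assessment
  of new-pack generalization would need a held-out-pack split, which the
  table API supports but which is not the default and not what the headline
  numbers measure. This is the main caveat when reading passing tests:
  they show the pipeline recovers concentrations under the stated noise
  structure, not that a deployed model transfers across reagent lots,
  scanners or illumination.

Default study layouts mirror the standard-series designs: chemical oxygen
demand 8 levels (0–100 mg O2/L, glucose standards converted by
COD = glucose · 192/180.16) × 5 packs; ammonium 6 levels (0–556 µM) × 3
packs; phosphate 5 levels (0–105 µM) × 3 packs; 10/5 pixels per pack —
hence 400/200, 180/90 and 150/75 train/validation rows. Simulated pack
images are 16×16 px by default: large enough for the 3×3 variance ranking
and 15 selected pixels, small enough that a full 40-pack study with all 83
channels derives in well under a second.

## Numerical and degenerate-input choices

- Channel math is integer-exact; merges use (a + b + 1) // 2.
- 16-bit rasters are downscaled to 8 bits with rounding on input; non-RGB
  or float images are rejected.
- NMAE with zero range, CV with zero mean, PCA with fewer than two rows,
  line fits with constant actuals, and stepwise with a constant target all
  raise typed errors rather than returning NaN.
- Stepwise iteration is capped at 4 × (number of candidates) + 4 steps per
  restart as a cycle guard; with p_in ≤ p_out a fresh entry cannot be
  removed in the same sweep, so the cap is never reached in practice.
- Seeds: every stochastic component (curve jitter, pack gains, pixel noise,
  tie-breaking, weight initialization) takes an explicit seed; derived
  per-pack seeds come from a single master generator.

## Known limitations

- CMYK and L\*a\*b\* encodings approximate editor conventions; they are not
  bit-compatible with any specific ICC engine, so coefficients of a linear
  model fitted under one separation convention should not be applied to
  channels produced under another.
- The simulator does not model reagent kinetics, spectral effects,
  semitransparent pack optics, JPG compression artifacts, or spatial
  gradients within a pack; its noise is stationary and multiplicative.
- The network reports no uncertainty; for intervals, bootstrap over packs.
- Stepwise inference p-values are nominal (selection is not accounted for);
  the procedure is used here as the field uses it, as a model-selection
  heuristic with a collinearity guard.
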