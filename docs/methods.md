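# Methods

## The measurement model behind the generator

A sample of tea powder spiked with `c` mg of talc per g of tea is modelled
as a Beer–Lambert mixture on a fixed wavenumber grid:

    A_s(w) = g_s · [ T_s(w) + c_s · κ · K(w) ] + β0_s + β1_s (w − w̄) + ε_s(w)

* `K(w)` — pure talc spectrum: Gaussian bands at 1016 (dominant), 995,
  1050, 1182, 1249, 1340, 1444, 1631 and 2296 cm⁻¹ plus a weak smooth
  background. Band positions follow the standard talc assignments
  (Si–O–Si stretches in 990–1055, carbonate near 1444, O–H near 1631,
  Si–H near 2296); heights and FWHMs are package defaults exposed in
  `SyntheticConfig`.
* `T_s(w)` — per-sample tea spectrum: broad bands at 1050, 1401, 1617,
  2920 and 3117 cm⁻¹ on a slowly decaying background. Each band height and
  the background amplitude carry an independent per-sample multiplier
  1 + N(0, `matrix_jitter_sd`) because distinct tea samples differ in
  composition. This term matters: with a perfectly fixed matrix the dose
  would be confounded with overall spectrum scale (the SNV closure
  effect), and every channel — not just the talc bands — would act as a
  clean dose sensor.
* `g_s ~ 1 + N(0, multiplicative_scale_sd)` — multiplicative scatter;
  `β0_s, β1_s` — per-spectrum affine baseline drift; `ε_s` — additive
  noise, convolved with a Gaussian line shape of FWHM `resolution_fwhm`
  (variance-preserving). The line-shape correlation reflects a
  spectrometer that samples (~1 cm⁻¹ spacing) finer than its optical
  resolution (4 cm⁻¹); without it, white noise would reward physically
  impossible noise-averaging across adjacent channels and bias selection
  toward diffuse subsets.
* κ (`kappa`, AU per mg/g) scales the talc contribution; the default 0.06
  puts the talc signal at the top dose near 10% of the tea apex, i.e. the
  adulteration is invisible to the eye.

Defaults (all in `default_config()`): 3700 grid points on [400, 4000] cm⁻¹
so trimming 500 + 400 points leaves exactly 2800 variables; 13 dose levels
0.00–1.50 mg/g with seven calibration levels × 20 replicates (140 samples)
and six prediction levels × 12 replicates (72); additive_sd = 0.010 AU,
multiplicative_scale_sd = 0.05, baseline offset/slope sd = 0.01 AU /
5·10⁻⁶ AU·cm, resolution_fwhm = 4 cm⁻¹, matrix_jitter_sd = 0.03. The point
count is prioritised over the printed trimmed endpoints (the default
trimmed grid spans ≈887–3611 cm⁻¹) because every percentage in the
analysis is taken out of 2800 variables. The additive noise floor was set
so that the full-spectrum SNV + PLS model lands at the accuracy scale an
FT-IR study of this design reports (RMSEP ≈ 0.1 mg/g), rather than at
numerical perfection. The dose-level list is used verbatim even though one
printed level (0.15 mg/g for 0.50 mg in 4.00 g) is not the exact quotient;
`mass_to_dose` performs the exact arithmetic when asked. One integer seed
expands into independent substreams (gain, baseline, additive noise,
matrix jitter), so enabling one noise source never perturbs the draws of
another.

## Preprocessing

Trimming is positional (drop the first/last N points), applied before any
treatment. The compared treatments are row-wise:

* smoothing — centred moving average, default window 9 points, window
  shrinking symmetrically at the edges (the simplest defensible reading of
  an unspecified "smoothing");
* normalize — division by the spectrum maximum (a common IR convention); a
  unit-length variant is available for comparison;
* SNV — (x − mean)/sd with the sample (n−1) standard deviation, the
  dominant chemometrics convention. SNV's affine invariance
  snv(a + b·x) = snv(x) is exactly the mechanism that removes the
  generator's gain and offset distortions, and is asserted as a property
  test.

## PLS and model assessment

PLS1 uses NIPALS with single-response deflation; for one response the
inner loop converges in a single step, so each latent variable costs three
matrix–vector products. X is column-mean-centred but not variance-scaled
(spectroscopy convention; SNV already standardises rows). The component
count of every reported model is chosen by leave-one-out RMSECV with
smaller-count tie-breaking; the pipeline caps candidate counts at 10 (13
dose levels and a single adulterant leave a small latent space), while the
standalone `loo_cv` default cap is 20.

LOO-CV exploits an exact reduction: every PLS1 quantity depends on the
predictors only through row-space inner products, so when p > n the matrix
is first rotated onto its right singular vectors (an n-dimensional
representation) without changing any fold's prediction. A test verifies
the reduction against explicit per-fold NIPALS refits on the raw matrix.

R is the Pearson correlation between measured and predicted dose; RMSE
values are in mg/g. PCA (delegated to scikit-learn behind the package
surface) reports per-component explained-variance percentages that sum to
100.

## Selection cascade

* **biPLS** splits the p variables into 20 contiguous intervals of
  near-equal width (remainder to the leading intervals), then greedily
  removes, at each round, the interval whose removal gives the lowest
  LOO-RMSECV, all the way down to one interval; the interval set with the
  global-minimum RMSECV along the path is returned (ties → earlier step).
  On toy problems this is verified against exhaustive interval-subset
  enumeration.
* **CARS** runs N = 50 Monte-Carlo rounds with an 80% calibration
  fraction. The exponentially decreasing schedule r_i = a·e^(−k·i) is
  pinned by r₁ = 1 and r_N = 2/p (a = e^k, k = ln(p/2)/(N−1)). Per round:
  fit PLS on a random sample subset, weight variables by normalised |b|,
  keep the schedule's top count (enforced selection), then draw p weighted
  bootstrap samples from the kept set and retain the distinct draws
  (adaptive reweighting). Drawing p times — rather than only the
  schedule's count — is essential: with fewer draws the distinct-draw
  attrition (~50% per round) outruns the schedule and the eligible set
  collapses within a dozen rounds instead of tracking the schedule across
  all N. If the distinct draws ever fall below two, the enforced set is
  kept unchanged. The round whose surviving set has the lowest LOO-RMSECV
  wins (earlier round on ties).
* **SPA** grows, from every possible start column, a chain that repeatedly
  adds the candidate with the largest norm orthogonal to the span of the
  chosen columns (verified against an independent pivoted Gram–Schmidt
  oracle), and scores every chain prefix by the closed-form (hat-matrix)
  LOO-RMSECV of an ordinary least-squares model — SPA subsets are built to
  be well-conditioned, so plain multiple regression is the appropriate
  scorer. Minimum RMSECV wins; ties prefer the shorter prefix, then the
  smaller start index. Subsets whose hat matrix has a leverage-one sample
  are rejected as unscorable.

Each stage consumes only the survivors of the previous one and reports
indices in original-grid coordinates, so containment
spa ⊆ cars ⊆ bipls ⊆ all is structural. Selected wavenumbers are displayed
rounded to integer cm⁻¹ but kept at full precision internally. All
stochastic stages derive from explicit seeds and are bit-reproducible.

## ELM

Inputs are scaled per feature to [−1, 1] using calibration min/max (an
unscaled absorbance would saturate the sigmoid); zero-range features pass
through at 0 with a warning. Hidden weights and biases are drawn from
U[−1, 1] once per fit; the output layer is the minimum-norm least-squares
solution β = H⁺y (no ridge term by default). The node sweep (default 1–80)
scores each count by LOO-RMSECV on the calibration set only, redrawing the
hidden layer for every fold fit from one seeded stream; prediction-set
data never enters model selection.

## Pipeline conventions

The preprocessing comparison ranks treatments by R_P with minimum RMSEP
breaking ties, and the selection cascade runs on the winner (override via
`selection_input`). The final report ranks all models by RMSEP and prints
both orderings with an agreement flag, since R_P and RMSEP can disagree
about the "best" model. Metrics are printed to 3 decimals, percentages to
2 (rounded half-up, with the exact value alongside). Stage timings and
variable counts are logged at info level, RMSECV traces at debug. The
report carries the master seed and a config hash; two runs with the same
config and seed produce identical reports up to the timestamp.

## What the generator does and does not show

Passing tests on synthetic data demonstrate that the implementation
recovers a known linear dose response under gain/baseline/additive
distortions at realistic signal-to-noise, that SNV removes exactly the
distortions it is supposed to remove, and that the selection cascade
shrinks 2800 variables to a sub-1% subset that still supports an accurate
model. They do not demonstrate performance on real tea spectra: the
generator's matrix variability is a low-rank band-height jitter rather
than true compositional diversity, peak shapes are ideal
Gaussians/Lorentzians without water-vapour or CO₂ interference, and the
dose response is perfectly linear with no detector nonlinearity.

A consequence worth stating: the final SPA subset mixes talc-band channels
with off-band reference channels. That is not a defect — a
minimal-redundancy selector needs reference channels to correct matrix and
baseline variation (the band-height jitter alone spans a rank-6 subspace),
so concentration of *all* selections onto talc band centres should not be
expected from this cascade, and in practice roughly a quarter to half of
the final wavenumbers fall within ±10 cm⁻¹ of a configured talc centre
depending on seed and noise regime.

## Numerical choices

NIPALS stops early when the weight vector or score norm vanishes
(tolerance 1e−12 relative): a constant response yields the zero-coefficient
model, while exhausting the predictor rank below an explicitly requested
component count raises an error. Ties everywhere (component counts,
interval elimination, CARS runs, SPA prefixes, ELM node counts) break
toward the smaller index/count/earlier step to keep runs deterministic.
Degenerate inputs (all-zero spectrum for normalization, zero-spread
spectrum for SNV, over-trimming, doses outside the level design) raise
errors naming the offending quantity.
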