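# Methods

## Synthetic cohort model

The generator emulates the statistical structure of a two-class thyroid
tissue Raman study: `n_per_class` tissues per class (default 30) scanned at
`sites_per_tissue` locations (default 2) on a uniform 400–1800 cm⁻¹ axis at
1 cm⁻¹ spacing, which covers every band of interest with margin.  A site
spectrum is

    I(x) = Σ_k L(x; c_k, a_k·j_k, w_k) + s · B(x) + ε(x),  clipped at 0

with `L` a Lorentzian of centre `c_k`, height `a_k` and FWHM `w_k`
(default 15 cm⁻¹, a typical solid-tissue Raman linewidth), `B` a degree-5
polynomial fluorescence background evaluated in the scaled coordinate
`u = (x − x₀)/(x₁ − x₀)` (default coefficients chosen positive over the whole
axis), and `ε` i.i.d. Gaussian noise of sd `noise_sd` (default 2, i.e. 2% of
the tallest band) — a shot-noise approximation.  Clipping at zero reflects
CCD counts.

Benign bands sit at 591, 649, 723, 801, 975, 1019, 1654 cm⁻¹ and malignant
bands at 591, 649, 1019, 1309, 1423, 1687 cm⁻¹; the shared bands
(591/649/1019) carry identical default heights in both classes so class
contrast comes only from the class-specific bands.  Heights were chosen in
the 40–100 range with the strong C–C band (1019) tallest, as in tissue
spectra.

Variation is specimen-level where biology is specimen-level: each tissue
draws one lognormal jitter per band height (sd 10%) and one lognormal
fluorescence scale (sd 10%), shared by its scan sites; only the noise is
site-specific.  All draws derive from a single integer seed via
`SeedSequence([seed, crc32(tissue_id), site])`, so equal seeds give
bit-identical cohorts and the per-tissue draws are independent of cohort
size or ordering.

**What the generator does not emulate:** instrument axis drift and response
curvature (spectra are born calibrated), cosmic-ray spikes, heteroscedastic
shot noise, peak-position shifts or width changes between classes,
within-class biochemical subtypes, and any correlation between bands beyond
the shared per-tissue jitter.  Passing tests therefore demonstrate that the
analysis chain is correct and recovers planted structure under realistic
noise — not that real thyroid tissue is classified at any particular
accuracy.

## Preprocessing

* **Calibration** is a rigid axis shift mapping the observed silicon line to
  520.7 cm⁻¹.  The instrument constant 1445 cm⁻¹ (CH₂ deformation) is
  exposed as `preprocess.CH2_DEFORMATION_BAND` for optional intensity-
  reference checks only; it plays no role in axis calibration.
* **Response correction** divides by the white-light reference and rescales
  to preserve the input's trapezoidal area, so later area normalization is
  comparable across instruments.  The reference must be strictly positive.
* **Fluorescence removal** operationalizes "fifth-order polynomial fitting"
  as the iterative modified polyfit: fit degree 5, clamp the working
  spectrum to the fit, refit; stop when the background changes by less than
  `poly_tol` (default 1e-6) relative to the input maximum, or after
  `poly_max_iter` (default 100) iterations.  Fits use the numerically
  stable scaled-domain polynomial class.
* **Rubber band** is the lower convex hull of (axis, intensity), built by a
  monotone-chain scan and linearly interpolated between vertices; corrected
  intensities are exactly zero at the endpoints and every hull vertex, and
  non-negative everywhere (interpolation round-off is clipped).
* **Area normalization** uses the trapezoidal rule on the uniform axis;
  applying it twice is a no-op.  The composed pipeline refuses spectra whose
  residual area after background removal is below 1e-8 of the input's
  absolute area: such input was pure background and normalizing it would
  only amplify fit noise.

Steps run in the order listed (polynomial before rubber band).  Every
intermediate is retrievable (`return_stages=True`) and logged at debug
level.

## Peak analysis

Peaks are local maxima thresholded on **prominence**, which is robust to
residual baseline, with a minimum separation of 10 cm⁻¹ (default) — below
the smallest gap between distinct reported bands.  The default threshold is
3× a robust noise estimate: 1.4826·MAD of the first difference divided by
√2 (differencing doubles the noise variance); on an exactly noiseless
spectrum this estimate degenerates, and a small fraction (1e-6) of the
intensity range is used instead.

Two class means are compared by greedy nearest-first matching of their peak
lists within a 5 cm⁻¹ tolerance; matched positions are reported as pair
midpoints, making the comparison symmetric under argument swap.  Band
assignment maps each peak to the nearest table entry within the same
tolerance (range entries match at distance zero inside the range).  The
packaged table reproduces the published assignment list as printed; since
printed tables may place distinct assignments closer than the tolerance
(1684 vs 1687 cm⁻¹ here), the table type permits overlap and nearest-band
matching resolves it.

## Discriminant classification and cross-validation

Features are trapezoidal band integrals over centre ± 8 cm⁻¹ windows.  The
band centres are **derived per training fold** as the union of the two
training-class-mean peak positions (merged within 5 cm⁻¹, clipped to windows
that fit the axis), so feature selection never sees the held-out tissue; a
principal-component projection mode (components fitted per fold) is
available for dense features.

The classifier is the two-class linear discriminant: class means, pooled
within-class covariance shrunk toward a scaled identity with the
Ledoit–Wolf analytic weight (keeping the discriminant defined when features
outnumber tissues), empirical training priors, and prediction by the larger
linear discriminant score.  Exact score ties predict benign — the
non-malignant call.  With shrinkage fixed to zero the fit reproduces a
standard reference LDA implementation exactly (tested).

Cross-validation is leave-one-**tissue**-out: all site spectra of the
held-out tissue are excluded, preprocessing is per-spectrum (no fitted
parameters, hence no leakage), features and discriminant are refitted per
fold, and the held-out tissue is predicted from its site-averaged spectrum.
Fold isolation is verified by corrupting a held-out tissue and checking that
no other prediction moves.

## Diagnostic and design statistics

Per-class correct rates come with exact Clopper–Pearson intervals
(beta-quantile form, validated against the closed-form quantiles).  The
study's tables label the benign-row rate "sensitivity" and the malignant-row
rate "specificity"; the report keeps neutral field names and applies that
mapping only in the display block.  Displayed percentages truncate (not
round) to one decimal — the convention that prints 25/28 as 89.2% — while
all comparisons in code use the untruncated rates.

Cohen's *d* uses the pooled (n−1)-weighted standard deviation.  Two-sample
t-test power is computed from the noncentral *t* distribution with
ncp = d·√(n/2) and df = 2n−2, validated against a 10⁵-replicate Monte-Carlo
simulation to within 0.01.  The minimum sample size uses the documented
two-proportion formula n = z²₁₋α/₂·(1 + 1/κ)·p̄(1−p̄)/δ² with p̄ the mean of
the reference proportion and the proportion δ below it, rounded up; at the
study's stated inputs (p = 0.9365, δ = 0.2, κ = 1) it gives 27, in the
mid-20s.  Neither the published power of 0.87 nor the published minimum of
26 is recovered exactly from the stated inputs under these standard
formulas; the operations are validated against independent oracles instead
of those printed values.

## Feature-table preparation

Half-minimum imputation fills each missing entry with half of that
*feature's* minimum observed value (the metabolomics convention; a global
minimum would couple unrelated analytes).  The IQR filter uses
linear-interpolation quartiles, stated explicitly because quartile
conventions differ.  Standardization is (x − mean)/sd with the n−1
denominator.  The canonical order impute → filter → standardize leaves no
missing values and never adds features.  This toolkit is standalone — it is
not wired into the Raman pipeline.

## Problem sizes and numerical tolerances

The test suite exercises full study-sized cohorts (30 tissues per class,
two sites) for the separable-recovery check and 20 seeds of 15 + 15
single-site null cohorts for the chance-level check, comparing the 20-seed
mean accuracy with the central 95% binomial band around 0.5 at the
per-cohort fold count (leave-one-out folds are correlated, so a pooled-n
band would be anti-conservative; the mean-over-seeds against the per-cohort
band is the robust form of the check).  Hull and quadrature oracles run on
200–1401-point spectra with 1e-8 absolute agreement; polynomial
annihilation is required to 1e-6 relative; normalized areas to 1e-9.

## Known limitations

Real instrument exports often need cosmic-ray removal and smoothing, which
are deliberately out of scope.  The JCAMP-DX reader handles plain tabular
layouts only.  The discriminant is strictly two-class; pathology subtypes
are not modelled.  Rate display truncation cannot reproduce conventionally
rounded percentages (29/30 prints 96.6%, not 96.7%), so numeric comparisons
should always use the rate fields, not the display strings.
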