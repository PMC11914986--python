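# ramandx

Raman-spectroscopy diagnostics for thyroid tumours: can the Raman spectrum of
a fresh tissue specimen tell a benign nodular goitre from a papillary thyroid
carcinoma?  `ramandx` implements the complete analysis chain used to answer
that question — synthetic tissue-spectrum simulation, the standard five-step
spectral preprocessing chain, characteristic-peak analysis with biomolecular
band assignment, and leave-one-tissue-out linear-discriminant classification
with exact diagnostic confidence intervals — as a tested, reusable Python
package for spectroscopists and clinical-chemometrics researchers.

## The method

Each tissue is scanned at two sites (532 nm, 10 mW, 10 s); every spectrum
passes through

1. wavenumber calibration against the 520.7 cm⁻¹ silicon phonon line,
2. instrument response correction with a white-light/BaSO₄ reference,
3. fluorescence removal by iterative fifth-order polynomial fitting,
4. rubber-band baseline correction (lower convex hull between the spectrum
   endpoints), and
5. area normalization (each point divided by the total integrated intensity),

after which the tissue is represented by the mean spectrum of its two sites.
Benign class means show bands at 591, 649, 723, 801, 975, 1019 and 1654 cm⁻¹;
malignant class means at 591, 649, 1019, 1309, 1423 and 1687 cm⁻¹, with the
nucleic-acid phosphodiester band at **1309 cm⁻¹** the malignant hallmark.

Classification is a two-class linear discriminant on band-integral features
(pooled within-class covariance with Ledoit–Wolf shrinkage toward a scaled
identity, empirical priors), validated **leave-one-tissue-out**: both site
spectra of the held-out tissue leave the training set together, the feature
bands and the discriminant are re-derived per fold, and the 2×2 confusion
matrix accumulated over folds yields per-class correct rates with exact
Clopper–Pearson intervals.  Cohen's *d*, noncentral-*t* two-sample power and
a two-proportion minimum-sample-size formula cover the study-design
statistics, and a small feature-table toolkit (half-minimum imputation,
IQR filtering, standardization) handles GC–MS-style data preparation.

No spectra from the original study are public, so the package ships a
first-class synthetic cohort generator (Lorentzian bands + polynomial
fluorescence + Gaussian noise, specimen-level variation, one seed) that
reproduces the statistical structure the analysis assumes.

## Worked example

```python
import ramandx as r

# 1. diagnostic metrics from cross-validated counts
report = r.metrics_from_confusion(r.ConfusionMatrix([[25, 5], [3, 25]]))
d = report.to_dict()["display"]
print(f"sensitivity {d['sensitivity']}  specificity {d['specificity']}  accuracy {d['accuracy']}")
print(f"95% CI benign {report.ci_benign[0]:.3f}-{report.ci_benign[1]:.3f}, "
      f"malignant {report.ci_malignant[0]:.3f}-{report.ci_malignant[1]:.3f}")

# 2. synthetic cohort, noiseless, class-mean comparison
cohort = r.simulate_cohort(r.default_config(n_per_class=5, noise_sd=0.0))
mb = r.preprocess_pipeline(r.class_mean_spectrum(cohort, "benign"))
mm = r.preprocess_pipeline(r.class_mean_spectrum(cohort, "malignant"))
diff = r.differential_peaks(mb, mm)
print("shared bands (cm^-1):        ", diff.shared.tolist())
print("malignant-only bands (cm^-1):", diff.unique_to_b.tolist())
for a in r.assign_peaks(r.detect_peaks(mm)):
    print(f"  {a.position:7.1f}  {a.substance or 'unassigned'}")

# 3. leave-one-tissue-out discriminant classification
cm, _ = r.leave_one_tissue_out(cohort)
print("confusion:", cm.counts.tolist())
```

prints

```
sensitivity 83.3%  specificity 89.2%  accuracy 86.2%
95% CI benign 0.653-0.944, malignant 0.718-0.977
shared bands (cm^-1):         [591.0, 649.0, 1019.0]
malignant-only bands (cm^-1): [1309.0, 1423.0, 1687.0]
    591.0  unassigned
    649.0  unassigned
   1019.0  Symmetrically telescopic C-C skeleton
   1309.0  Phosphodiester group in nucleic acid
   1423.0  unassigned
   1687.0  Tryptophan
confusion: [[5, 0], [0, 5]]
```

The first block turns the cross-validated confusion counts (25/30 benign and
25/28 malignant tissues called correctly) into the per-class rates — 83.3%
"sensitivity" and 89.2% "specificity" in the study's labelling, shown with
truncating one-decimal display — plus their exact 95% binomial intervals.
The second block recovers the shared and class-specific bands from a
noiseless synthetic cohort and annotates the malignant mean's peaks against
the packaged band table; the third classifies every tissue leave-one-out
(a perfectly diagonal confusion matrix on this cleanly separated cohort).

A `ramandx` console command wraps the same operations
(`simulate`, `preprocess`, `classify`, `report`, `prep-table`); see
`ramandx --help`.

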