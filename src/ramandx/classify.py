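"""Discriminant classification with leave-one-tissue-out cross-validation,
diagnostic metrics with exact binomial intervals, and the study-design
statistics (Cohen's d, two-sample t-test power, minimum sample size).

The classifier is a two-class linear discriminant: class means with a pooled
within-class covariance shrunk toward a scaled identity (Ledoit-Wolf weight),
empirical priors, and the decision rule

    predict argmax_k  x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k

with ties broken in favour of the benign class (the non-malignant call).

Cross-validation holds out one *tissue* per fold: every scan-site spectrum of
the held-out tissue leaves the training set together, the feature bands are
re-derived from the training tissues only, the discriminant is refitted, and
the held-out tissue is predicted from its site-averaged spectrum.  Folds
accumulate into a 2x2 confusion matrix in (benign, malignant) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import ledoit_wolf
from statsmodels.stats.proportion import proportion_confint

from .peaks import DEFAULT_MATCH_TOLERANCE, detect_peaks
from .preprocess import PreprocessConfig, preprocess_pipeline
from .spectra import Cohort, LABELS, RamanSpectrum

__all__ = [
    "FeatureSpec",
    "DiscriminantModel",
    "ConfusionMatrix",
    "DiagnosticReport",
    "PowerResult",
    "extract_features",
    "fit_discriminant",
    "leave_one_tissue_out",
    "metrics_from_confusion",
    "cohens_d",
    "power_two_sample",
    "min_sample_size",
    "truncate_percent",
]

DEFAULT_BAND_HALFWIDTH = 8.0


@dataclass(frozen=True)
class FeatureSpec:
    """How spectra become feature vectors.

    ``peak_bands`` mode integrates intensity over ``center +- halfwidth``
    windows; with ``band_centers=None`` the centers are derived per training
    fold as the union of the two class-mean peak positions.  ``projection``
    mode uses principal-component scores, with the components fitted on the
    training fold only.
    """

    mode: str = "peak_bands"
    band_centers: tuple | None = None
    band_halfwidth: float = DEFAULT_BAND_HALFWIDTH
    n_components: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("peak_bands", "projection"):
            raise ValueError(f"unknown feature mode {self.mode!r}")
        if self.band_halfwidth <= 0:
            raise ValueError("band_halfwidth must be positive")
        if self.mode == "peak_bands" and self.band_centers is not None and not self.band_centers:
            raise ValueError("peak_bands mode needs at least one band center")


def extract_features(spectrum: RamanSpectrum, spec: FeatureSpec) -> np.ndarray:
    """Band-integral feature vector for one spectrum.

    Each feature is the trapezoidal integral of intensity over the window
    ``[center - h, center + h]`` restricted to grid points inside it.
    Projection-mode feature extraction is fold-dependent and lives in the
    cross-validation driver.
    """
    if spec.mode != "peak_bands":
        raise ValueError("extract_features handles peak_bands mode; projection is fold-fitted")
    if spec.band_centers is None:
        raise ValueError("band_centers must be resolved before extraction")
    x = spectrum.axis.points
    y = spectrum.intensity
    feats = np.empty(len(spec.band_centers))
    for k, c in enumerate(spec.band_centers):
        lo, hi = c - spec.band_halfwidth, c + spec.band_halfwidth
        if lo < x[0] or hi > x[-1]:
            raise ValueError(f"band [{lo}, {hi}] extends outside the axis")
        mask = (x >= lo) & (x <= hi)
        feats[k] = np.trapezoid(y[mask], x[mask])
    return feats


@dataclass
class DiscriminantModel:
    """Fitted two-class linear discriminant."""

    classes: tuple
    class_means: np.ndarray          # (n_classes, n_features)
    pooled_covariance: np.ndarray    # shrunk, symmetric positive-definite
    shrinkage: float
    priors: np.ndarray

    _precision: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not np.allclose(self.pooled_covariance, self.pooled_covariance.T):
            raise ValueError("covariance must be symmetric")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        self._precision = np.linalg.inv(self.pooled_covariance)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant score per class, up to the shared -x'S^-1 x/2
        term; higher is more likely."""
        X = np.atleast_2d(X)
        scores = np.empty((X.shape[0], len(self.classes)))
        for k, mu in enumerate(self.class_means):
            w = self._precision @ mu
            scores[:, k] = X @ w - 0.5 * mu @ w + np.log(self.priors[k])
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        # argmax returns the first maximum, so exact ties fall to classes[0]
        # == benign by the (benign, malignant) ordering
        return np.asarray(self.classes)[np.argmax(scores, axis=1)]


def fit_discriminant(
    features: np.ndarray, labels, shrinkage: float | str = "auto"
) -> DiscriminantModel:
    """Fit the two-class linear discriminant with shrunk pooled covariance.

    ``shrinkage="auto"`` estimates the blend weight toward the scaled
    identity with the Ledoit-Wolf analytic rule on within-class-centred
    data; a float in [0, 1] fixes it.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("features must be a 2-D matrix with >= 1 column")
    classes = tuple(c for c in LABELS if c in y) or tuple(np.unique(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    centred = np.empty_like(X)
    means = np.empty((2, X.shape[1]))
    priors = np.empty(2)
    for k, c in enumerate(classes):
        mask = y == c
        if mask.sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[k] = X[mask].mean(axis=0)
        centred[mask] = X[mask] - means[k]
        priors[k] = mask.mean()
    if shrinkage == "auto":
        cov, lam = ledoit_wolf(centred, assume_centered=True)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
        n = X.shape[0]
        emp = centred.T @ centred / (n - 2)  # pooled, n - K denominator
        mu = np.trace(emp) / emp.shape[0]
        cov = (1 - lam) * emp + lam * mu * np.eye(emp.shape[0])
    if lam == 0.0 and np.linalg.matrix_rank(cov) < cov.shape[0]:
        raise ValueError("degenerate (singular) pooled covariance; use shrinkage")
    cov = 0.5 * (cov + cov.T)
    return DiscriminantModel(classes, means, cov, float(lam), priors)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, rows = true label, columns = predicted, (benign, malignant)."""

    counts: np.ndarray
    labels: tuple = LABELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 2) or np.any(counts < 0):
            raise ValueError("counts must be a 2x2 non-negative integer matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        idx = [f"true_{l}" for l in self.labels]
        cols = [f"pred_{l}" for l in self.labels]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


@dataclass(frozen=True)
class DiagnosticReport:
    """Per-class correct rates with exact Clopper-Pearson intervals.

    The study's tables call the benign-row rate "sensitivity" and the
    malignant-row rate "specificity"; the fields here are neutral per-class
    correct rates, with that mapping applied only at display time.
    """

    benign_correct_rate: float
    malignant_correct_rate: float
    overall_accuracy: float
    ci_benign: tuple
    ci_malignant: tuple
    n_folds: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for r in (self.benign_correct_rate, self.malignant_correct_rate, self.overall_accuracy):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for ci, r in ((self.ci_benign, self.benign_correct_rate),
                      (self.ci_malignant, self.malignant_correct_rate)):
            if not ci[0] - 1e-12 <= r <= ci[1] + 1e-12:
                raise ValueError("confidence interval must contain its point estimate")

    def to_dict(self) -> dict:
        return {
            "benign_correct_rate": self.benign_correct_rate,
            "malignant_correct_rate": self.malignant_correct_rate,
            "overall_accuracy": self.overall_accuracy,
            "ci_benign": list(self.ci_benign),
            "ci_malignant": list(self.ci_malignant),
            "n_folds": self.n_folds,
            "alpha": self.alpha,
            "display": {
                "sensitivity": f"{truncate_percent(self.benign_correct_rate)}%",
                "specificity": f"{truncate_percent(self.malignant_correct_rate)}%",
                "accuracy": f"{truncate_percent(self.overall_accuracy)}%",
            },
        }


def truncate_percent(rate: float, decimals: int = 1) -> float:
    """Percentage truncated (not rounded) to *decimals* places, the display
    convention that prints 25/28 as 89.2%."""
    factor = 10 ** decimals
    return np.trunc(rate * 100.0 * factor + 1e-9) / factor


def metrics_from_confusion(cm: ConfusionMatrix, alpha: float = 0.05) -> DiagnosticReport:
    """Per-class correct rates, overall accuracy, and exact binomial CIs."""
    counts = cm.counts
    row = cm.row_totals()
    if np.any(row == 0):
        raise ValueError("each true class needs at least one fold")
    benign_rate = counts[0, 0] / row[0]
    malignant_rate = counts[1, 1] / row[1]
    overall = np.trace(counts) / cm.total
    ci_b = proportion_confint(counts[0, 0], row[0], alpha=alpha, method="beta")
    ci_m = proportion_confint(counts[1, 1], row[1], alpha=alpha, method="beta")
    return DiagnosticReport(
        benign_correct_rate=float(benign_rate),
        malignant_correct_rate=float(malignant_rate),
        overall_accuracy=float(overall),
        ci_benign=(float(ci_b[0]), float(ci_b[1])),
        ci_malignant=(float(ci_m[0]), float(ci_m[1])),
        n_folds=cm.total,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Leave-one-tissue-out cross-validation
# ---------------------------------------------------------------------------

def _tissue_spectra(cohort: Cohort, preprocess_config, white_reference):
    """Preprocess every site spectrum, then site-average per tissue."""
    out = {}
    for sample in cohort.samples:
        processed = [
            preprocess_pipeline(sp, white_reference=white_reference, config=preprocess_config)
            for sp in sample.site_spectra
        ]
        mean = np.mean([sp.intensity for sp in processed], axis=0)
        out[sample.tissue_id] = RamanSpectrum(
            processed[0].axis, mean, {"tissue_id": sample.tissue_id, "label": sample.label}
        )
    return out


def _fold_band_centers(train_spectra, train_labels, spec: FeatureSpec, axis):
    """Union of class-mean peak positions, merged within the match tolerance
    and clipped so every band window fits the axis."""
    centers: list[float] = []
    for label in LABELS:
        members = [sp for sp, l in zip(train_spectra, train_labels) if l == label]
        mean = RamanSpectrum(axis, np.mean([sp.intensity for sp in members], axis=0))
        centers.extend(detect_peaks(mean).positions)
    centers.sort()
    merged: list[float] = []
    for c in centers:
        if merged and c - merged[-1] <= DEFAULT_MATCH_TOLERANCE:
            merged[-1] = 0.5 * (merged[-1] + c)
        else:
            merged.append(c)
    h = spec.band_halfwidth
    usable = [c for c in merged if c - h >= axis.start and c + h <= axis.stop]
    return tuple(usable)


def leave_one_tissue_out(
    cohort: Cohort,
    feature_spec: FeatureSpec | None = None,
    preprocess_config: PreprocessConfig | None = None,
    white_reference: RamanSpectrum | None = None,
    shrinkage: float | str = "auto",
):
    """Leave-one-tissue-out cross-validation of the discriminant.

    One fold per tissue.  Within each fold the feature definition (band
    centers or principal components) and the discriminant are derived from
    the training tissues only; the held-out tissue is predicted from its
    site-averaged preprocessed spectrum.

    Returns ``(ConfusionMatrix, predictions)`` where ``predictions`` is a
    DataFrame with columns tissue_id, true, predicted, score (malignant
    minus benign discriminant score).
    """
    if feature_spec is None:
        feature_spec = FeatureSpec()
    n_per_class = {l: len(cohort.with_label(l)) for l in LABELS}
    for label, n in n_per_class.items():
        if n < 2:
            raise ValueError(f"need >= 2 tissues per class, {label} has {n}")
        if n - 1 < 2:
            raise ValueError(
                f"holding out a {label} tissue leaves {n - 1} training tissues; need >= 2"
            )
    tissue_spectra = _tissue_spectra(cohort, preprocess_config, white_reference)
    ids = [s.tissue_id for s in cohort.samples]
    labels = {s.tissue_id: s.label for s in cohort.samples}
    axis = cohort.samples[0].axis
    rows = []
    counts = np.zeros((2, 2), dtype=int)
    for held_out in ids:
        train_ids = [t for t in ids if t != held_out]
        train_sp = [tissue_spectra[t] for t in train_ids]
        train_y = [labels[t] for t in train_ids]
        if feature_spec.mode == "peak_bands":
            if feature_spec.band_centers is None:
                centers = _fold_band_centers(train_sp, train_y, feature_spec, axis)
            else:
                centers = feature_spec.band_centers
            fold_spec = FeatureSpec(
                "peak_bands", tuple(centers), feature_spec.band_halfwidth
            )
            X_train = np.vstack([extract_features(sp, fold_spec) for sp in train_sp])
            x_test = extract_features(tissue_spectra[held_out], fold_spec)
        else:  # projection: PCA fitted on training intensities only
            from sklearn.decomposition import PCA

            M = np.vstack([sp.intensity for sp in train_sp])
            pca = PCA(n_components=min(feature_spec.n_components, len(train_sp) - 1),
                      random_state=0)
            X_train = pca.fit_transform(M)
            x_test = pca.transform(tissue_spectra[held_out].intensity[None, :])[0]
        model = fit_discriminant(X_train, train_y, shrinkage=shrinkage)
        scores = model.decision_scores(x_test[None, :])[0]
        pred = model.predict(x_test[None, :])[0]
        true = labels[held_out]
        counts[LABELS.index(true), LABELS.index(pred)] += 1
        rows.append(
            {"tissue_id": held_out, "true": true, "predicted": str(pred),
             "score": float(scores[1] - scores[0])}
        )
    return ConfusionMatrix(counts), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Effect size, power, sample size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerResult:
    effect_size_d: float
    alpha: float
    n_per_group: int
    power: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0, 1]")


def cohens_d(values_a, values_b) -> float:
    """Cohen's d: mean difference over the pooled (n-1 weighted) sd."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def power_two_sample(
    d: float, n_per_group: int, alpha: float = 0.05, sides: int = 2
) -> PowerResult:
    """Power of the two-sample t test at effect size *d*, equal group sizes,
    via the noncentral t distribution (ncp = d * sqrt(n/2), df = 2n - 2)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    if sides == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    else:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = stats.nct.sf(tcrit, df, ncp)
    return PowerResult(float(d), float(alpha), int(n_per_group), float(power))


def min_sample_size(
    p_reference: float, delta: float, kappa: float = 1.0, alpha: float = 0.05
) -> int:
    """Minimum per-group size to distinguish a reference proportion from one
    *delta* lower, group-size ratio *kappa*, two-sided level *alpha*:

        n = z^2_{1-alpha/2} * (1 + 1/kappa) * pbar (1 - pbar) / delta^2

    with pbar the mean of ``p_reference`` and ``p_reference - delta``;
    rounded up.  Strictly decreasing in *delta*.
    """
    if not 0.0 < p_reference < 1.0:
        raise ValueError("p_reference must be in (0, 1)")
    if not 0.0 < delta < p_reference:
        raise ValueError("delta must be in (0, p_reference)")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p2 = p_reference - delta
    pbar = 0.5 * (p_reference + p2)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    n = z**2 * (1.0 + 1.0 / kappa) * pbar * (1.0 - pbar) / delta**2
    return int(np.ceil(n - 1e-12))
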