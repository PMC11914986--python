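"""Five-step spectral preprocessing chain for tissue Raman spectra.

The chain, applied in order:

1. **Wavenumber calibration** against the 520.7 cm^-1 silicon phonon line
   (rigid axis shift).
2. **Instrument response correction** by pointwise division with a white-light
   reference (tungsten lamp on a BaSO4 diffuse reflectance standard), rescaled
   to preserve the total spectral area.
3. **Fluorescence removal** by iterative ("modified polyfit") degree-5
   polynomial fitting: fit, clamp the working spectrum to the fit, refit,
   until the background estimate stops changing.
4. **Rubber-band baseline**: the lower convex hull of the spectrum, linearly
   interpolated between hull vertices, is subtracted, leaving non-negative
   band intensities that vanish at the endpoints.
5. **Area normalization**: divide by the trapezoidal integral so every
   spectrum has unit area.

Each step is its own function mapping RamanSpectrum -> RamanSpectrum;
``preprocess_pipeline`` composes them and can return every intermediate for
audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra import RamanSpectrum, WavenumberAxis

__all__ = [
    "PreprocessConfig",
    "calibrate_axis",
    "correct_response",
    "remove_fluorescence_poly5",
    "rubber_band_baseline",
    "area_normalize",
    "preprocess_pipeline",
    "SILICON_REFERENCE_CM1",
    "CH2_DEFORMATION_BAND",
]

logger = logging.getLogger("ramandx.preprocess")

#: Standard silicon phonon line used for wavenumber calibration (cm^-1).
SILICON_REFERENCE_CM1 = 520.7

#: CH2 deformation band (cm^-1), usable as an optional intensity-reference
#: check on tissue spectra; not part of the axis calibration.
CH2_DEFORMATION_BAND = 1445.0

# Residual area below this fraction of the input's absolute area means the
# spectrum was essentially pure background; normalizing it would only amplify
# fit noise, so the pipeline refuses.
_DEGENERATE_AREA_FRACTION = 1e-8


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the chain. ``poly_degree`` is 5 by construction of the method;
    it is exposed only so the background fit can be inspected at other
    degrees in exploratory work."""

    silicon_reference: float = SILICON_REFERENCE_CM1
    poly_degree: int = 5
    poly_max_iter: int = 100
    poly_tol: float = 1e-6
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.poly_max_iter < 1:
            raise ValueError("poly_max_iter must be >= 1")
        if self.poly_tol <= 0:
            raise ValueError("poly_tol must be positive")


def calibrate_axis(
    spectrum: RamanSpectrum, observed_reference: float, true_reference: float
) -> RamanSpectrum:
    """Rigidly shift the wavenumber axis so the observed reference line lands
    on its true position; intensities are untouched."""
    if not spectrum.axis.contains(observed_reference):
        raise ValueError(f"observed reference {observed_reference} outside axis range")
    if not spectrum.axis.contains(true_reference):
        raise ValueError(f"true reference {true_reference} outside axis range")
    delta = true_reference - observed_reference
    return spectrum.with_axis(spectrum.axis.shifted(delta))


def correct_response(spectrum: RamanSpectrum, white_reference: RamanSpectrum) -> RamanSpectrum:
    """Divide out the instrument spectral response, preserving total area.

    The white reference must be strictly positive on the identical axis.  The
    result is rescaled so its trapezoidal area equals the input's, keeping
    later area normalization comparable across instruments.
    """
    if spectrum.axis != white_reference.axis:
        raise ValueError("spectrum and white reference must share one axis")
    ref = white_reference.intensity
    if np.any(ref <= 0):
        raise ValueError("white reference must be strictly positive everywhere")
    corrected = spectrum.intensity / ref
    area_in = spectrum.area()
    area_out = float(np.trapezoid(corrected, spectrum.axis.points))
    if area_out != 0:
        corrected = corrected * (area_in / area_out)
    return spectrum.with_intensity(corrected)


def remove_fluorescence_poly5(
    spectrum: RamanSpectrum,
    config: PreprocessConfig | None = None,
    return_background: bool = False,
):
    """Subtract the fluorescence background by iterative degree-5 polyfit.

    Fit a degree-5 polynomial, replace every point lying above the fit by the
    fit (so peaks stop pulling the fit upward), refit, and repeat until the
    background estimate changes by less than ``poly_tol`` (relative to the
    input's scale) or ``poly_max_iter`` is reached.  Returns the corrected
    spectrum, optionally with the background estimate.
    """
    if config is None:
        config = PreprocessConfig()
    x = spectrum.axis.points
    y = spectrum.intensity
    degree = config.poly_degree
    if y.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree-{degree} removal")
    scale = float(np.max(np.abs(y)))
    if scale == 0.0:
        background = np.zeros_like(y)
        out = spectrum.with_intensity(background.copy())
        return (out, spectrum.with_intensity(background)) if return_background else out
    work = y.copy()
    background = np.zeros_like(y)
    for _ in range(config.poly_max_iter):
        fit = np.polynomial.Polynomial.fit(x, work, degree)
        new_background = fit(x)
        delta = float(np.max(np.abs(new_background - background)))
        background = new_background
        work = np.minimum(work, background)
        if delta < config.poly_tol * scale:
            break
    corrected = spectrum.with_intensity(y - background)
    if return_background:
        return corrected, spectrum.with_intensity(background)
    return corrected


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices (monotone-chain scan)."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # pop i2 if it lies on or above the chord i1 -> i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (x[i] - x[i1]) * (y[i2] - y[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def rubber_band_baseline(spectrum: RamanSpectrum):
    """Stretched rubber-band baseline between the spectrum endpoints.

    The baseline is the lower convex hull of ``(axis, intensity)`` linearly
    interpolated between hull vertices; subtracting it yields a non-negative
    spectrum that is exactly zero at both endpoints and at every hull vertex.

    Returns ``(baseline, corrected)`` as two spectra.
    """
    x = spectrum.axis.points
    y = spectrum.intensity
    if y.size < 3:
        raise ValueError("rubber-band baseline needs at least 3 points")
    idx = _lower_hull_indices(x, y)
    baseline = np.interp(x, x[idx], y[idx])
    corrected = y - baseline
    corrected[idx] = 0.0  # exact zeros at hull vertices despite fp interp
    np.maximum(corrected, 0.0, out=corrected)
    return spectrum.with_intensity(baseline), spectrum.with_intensity(corrected)


def area_normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Rescale so the trapezoidal area of the spectrum equals one."""
    area = spectrum.area()
    if area <= 0:
        raise ValueError(f"cannot normalize: non-positive spectral area {area}")
    return spectrum.with_intensity(spectrum.intensity / area)


def preprocess_pipeline(
    spectrum: RamanSpectrum,
    white_reference: RamanSpectrum | None = None,
    config: PreprocessConfig | None = None,
    observed_reference: float | None = None,
    return_stages: bool = False,
):
    """Run the full five-step chain in order.

    ``observed_reference`` is the silicon line's apparent position in this
    acquisition; omit it (or the white reference) to skip the corresponding
    instrument-correction step, as is natural for spectra that are already
    calibrated — e.g. simulated ones.  With ``return_stages=True`` the return
    value is ``(final, stages)`` where ``stages`` maps stage names to the
    intermediate spectra.
    """
    if config is None:
        config = PreprocessConfig()
    stages: dict[str, RamanSpectrum] = {"raw": spectrum}
    out = spectrum
    if observed_reference is not None:
        out = calibrate_axis(out, observed_reference, config.silicon_reference)
    stages["calibrated"] = out
    logger.debug("calibrated: axis %.1f..%.1f", out.axis.start, out.axis.stop)
    if white_reference is not None:
        out = correct_response(out, white_reference)
    stages["response_corrected"] = out
    out = remove_fluorescence_poly5(out, config)
    stages["fluorescence_removed"] = out
    baseline, out = rubber_band_baseline(out)
    stages["baseline"] = baseline
    stages["baseline_corrected"] = out
    if config.normalize:
        input_scale = float(np.trapezoid(np.abs(spectrum.intensity), spectrum.axis.points))
        if out.area() < _DEGENERATE_AREA_FRACTION * max(input_scale, 1e-300):
            raise ValueError(
                "degenerate spectrum: background removal left essentially no "
                "signal to normalize"
            )
        out = area_normalize(out)
    stages["normalized"] = out
    logger.debug("preprocessed %s: area=%.6f", spectrum.meta.get("tissue_id", "?"), out.area())
    return (out, stages) if return_stages else out
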