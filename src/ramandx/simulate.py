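"""Synthetic Raman cohort generator for benign vs malignant thyroid tissue.

Generated spectra are sums of Lorentzian bands on top of a smooth degree-5
polynomial fluorescence background, with additive Gaussian instrument noise,
clipped at zero (CCD counts cannot go negative).  The default configuration
places the benign-class bands at 591, 649, 723, 801, 975, 1019 and 1654 cm^-1
and the malignant-class bands at 591, 649, 1019, 1309, 1423 and 1687 cm^-1,
i.e. the two classes share the 591/649/1019 bands and differ in the rest, with
1309 cm^-1 (nucleic-acid phosphodiester) the malignant hallmark.

Biological and experimental variation is modelled at two levels:

* per **tissue**: a lognormal amplitude jitter on every band and a lognormal
  scale on the fluorescence background (fluorescence is specimen-level, so the
  two scan sites of a tissue share one background);
* per **site**: independent zero-mean Gaussian noise.

Everything is driven by a single integer seed; equal seeds give bit-identical
cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import (
    BENIGN,
    Cohort,
    LABELS,
    MALIGNANT,
    RamanSpectrum,
    TissueSample,
    WavenumberAxis,
    make_axis,
)

__all__ = [
    "PeakSpec",
    "GeneratorConfig",
    "lorentzian",
    "simulate_spectrum",
    "simulate_cohort",
    "default_config",
    "BENIGN_PEAKS_CM1",
    "MALIGNANT_PEAKS_CM1",
]

#: Class-specific band positions (cm^-1) the generator reproduces.
BENIGN_PEAKS_CM1 = (591.0, 649.0, 723.0, 801.0, 975.0, 1019.0, 1654.0)
MALIGNANT_PEAKS_CM1 = (591.0, 649.0, 1019.0, 1309.0, 1423.0, 1687.0)

#: Default Lorentzian FWHM (cm^-1): a typical solid-tissue Raman linewidth.
DEFAULT_FWHM = 15.0

# Default band heights (arbitrary counts).  Shared bands get the same height
# in both classes so that class contrast comes only from class-specific bands.
_DEFAULT_AMPLITUDES = {
    591.0: 60.0, 649.0: 55.0, 723.0: 45.0, 801.0: 50.0, 975.0: 40.0,
    1019.0: 100.0, 1654.0: 80.0, 1309.0: 70.0, 1423.0: 50.0, 1687.0: 75.0,
}

# Fluorescence background polynomial, degree 5 in the scaled coordinate
# u = (wavenumber - start) / (stop - start) in [0, 1]; positive on the axis.
_DEFAULT_BACKGROUND = (120.0, -80.0, 40.0, -10.0, 5.0, -2.0)

_JITTER_SIGMA = 0.1  # lognormal sd of per-tissue amplitude/background jitter


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian band: centre (cm^-1), height (counts), FWHM (cm^-1)."""

    center: float
    amplitude: float
    fwhm: float = DEFAULT_FWHM

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic cohort.

    ``background_coeffs`` are the 6 coefficients (constant first) of the
    degree-5 fluorescence polynomial evaluated in the scaled axis coordinate
    ``u = (x - start)/(stop - start)``; the scaling keeps the fit and the
    generator numerically well conditioned on wavenumber axes.
    """

    benign_peaks: tuple
    malignant_peaks: tuple
    background_coeffs: tuple = _DEFAULT_BACKGROUND
    noise_sd: float = 2.0
    n_per_class: int = 30
    sites_per_tissue: int = 2
    seed: int = 0
    axis: WavenumberAxis = field(default_factory=lambda: make_axis(400.0, 1800.0, 1.0))
    amplitude_jitter_sigma: float = _JITTER_SIGMA
    background_jitter_sigma: float = _JITTER_SIGMA

    def __post_init__(self) -> None:
        if not self.benign_peaks or not self.malignant_peaks:
            raise ValueError("both peak lists must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_per_class < 1 or self.sites_per_tissue < 1:
            raise ValueError("n_per_class and sites_per_tissue must be >= 1")
        if len(self.background_coeffs) != 6:
            raise ValueError("background_coeffs must have 6 entries (degree 5)")
        for pk in (*self.benign_peaks, *self.malignant_peaks):
            if not self.axis.contains(pk.center):
                raise ValueError(f"peak centre {pk.center} outside axis range")

    def peaks_for(self, label: str) -> tuple:
        if label == BENIGN:
            return self.benign_peaks
        if label == MALIGNANT:
            return self.malignant_peaks
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")


def default_config(**overrides) -> GeneratorConfig:
    """Configuration matching the study conditions: 30 tissues per class, two
    scan sites per tissue, the class band positions listed above, and noise at
    2% of the tallest band."""
    cfg = GeneratorConfig(
        benign_peaks=tuple(
            PeakSpec(c, _DEFAULT_AMPLITUDES[c]) for c in BENIGN_PEAKS_CM1
        ),
        malignant_peaks=tuple(
            PeakSpec(c, _DEFAULT_AMPLITUDES[c]) for c in MALIGNANT_PEAKS_CM1
        ),
    )
    return replace(cfg, **overrides) if overrides else cfg


def lorentzian(x: np.ndarray, center: float, amplitude: float, fwhm: float) -> np.ndarray:
    """Lorentzian line with peak height *amplitude* and full width *fwhm*."""
    hwhm = fwhm / 2.0
    return amplitude * hwhm**2 / ((x - center) ** 2 + hwhm**2)


def _background(config: GeneratorConfig) -> np.ndarray:
    x = config.axis.points
    u = (x - x[0]) / (x[-1] - x[0])
    return np.polynomial.polynomial.polyval(u, np.asarray(config.background_coeffs))


def _tissue_rng(seed: int, tissue_id: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(tissue_id.encode())]))


def _site_rng(seed: int, tissue_id: str, site: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(tissue_id.encode()), site])
    )


def _tissue_effects(config: GeneratorConfig, label: str, tissue_id: str, seed: int):
    """Per-tissue lognormal jitters, deterministic in (seed, tissue_id)."""
    rng = _tissue_rng(seed, tissue_id)
    n = len(config.peaks_for(label))
    amp = np.exp(rng.normal(0.0, config.amplitude_jitter_sigma, size=n))
    bg = float(np.exp(rng.normal(0.0, config.background_jitter_sigma)))
    return amp, bg


def simulate_spectrum(
    config: GeneratorConfig, label: str, tissue_id: str = "t0", site: int = 0,
    seed: int | None = None,
) -> RamanSpectrum:
    """Simulate one site spectrum.

    The same ``(config, label, tissue_id, site, seed)`` always yields a
    bit-identical spectrum; sites of one tissue share the tissue-level
    amplitude jitter and background scale but draw independent noise.
    """
    if seed is None:
        seed = config.seed
    peaks = config.peaks_for(label)
    x = config.axis.points
    amp_jitter, bg_scale = _tissue_effects(config, label, tissue_id, seed)
    signal = np.zeros_like(x)
    for pk, j in zip(peaks, amp_jitter):
        signal += lorentzian(x, pk.center, pk.amplitude * j, pk.fwhm)
    signal += bg_scale * _background(config)
    if config.noise_sd > 0:
        signal = signal + _site_rng(seed, tissue_id, site).normal(0.0, config.noise_sd, x.size)
    np.maximum(signal, 0.0, out=signal)
    meta = {
        "tissue_id": tissue_id, "site": site,
        "laser_nm": 532, "power_mW": 10, "exposure_s": 10, "label": label,
    }
    return RamanSpectrum(config.axis, signal, meta)


def simulate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Simulate the full two-class cohort described by *config*.

    Tissue ids are ``benign_01 .. benign_N`` and ``malignant_01 .. malignant_N``;
    each tissue carries ``sites_per_tissue`` spectra.
    """
    if config is None:
        config = default_config()
    samples = []
    for label in LABELS:
        for i in range(config.n_per_class):
            tissue_id = f"{label}_{i + 1:02d}"
            spectra = [
                simulate_spectrum(config, label, tissue_id, site, config.seed)
                for site in range(1, config.sites_per_tissue + 1)
            ]
            samples.append(TissueSample(tissue_id, label, spectra))
    return Cohort(samples)
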