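"""Peak detection, class-mean comparison and biomolecular band assignment.

Each tissue is represented by the mean of its scan-site spectra; class mean
spectra (benign, malignant) are means over those tissue averages.  Peaks are
local maxima thresholded on *prominence* — robust to residual baseline —
with a minimum separation in cm^-1.  Peaks of two class means are matched
within a tolerance to split them into shared and class-unique bands, and any
peak list can be annotated against a wavenumber -> biomolecule table (shipped
as a packaged CSV, user-replaceable).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .spectra import Cohort, RamanSpectrum, TissueSample

__all__ = [
    "PeakList",
    "AssignmentTable",
    "DifferentialPeaks",
    "PeakAssignment",
    "average_sites",
    "class_mean_spectrum",
    "detect_peaks",
    "differential_peaks",
    "assign_peaks",
    "default_assignment_table",
    "DEFAULT_MATCH_TOLERANCE",
    "DEFAULT_MIN_SEPARATION",
]

#: Default peak-matching tolerance (cm^-1); below the smallest gap between
#: distinct reported bands of the two classes.
DEFAULT_MATCH_TOLERANCE = 5.0
#: Default minimum separation between detected peaks (cm^-1).
DEFAULT_MIN_SEPARATION = 10.0


@dataclass(frozen=True)
class PeakList:
    """Detected band positions with their heights and prominences."""

    positions: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        hts = np.asarray(self.heights, float)
        prom = np.asarray(self.prominences, float)
        if not (pos.size == hts.size == prom.size):
            raise ValueError("positions, heights, prominences must have equal length")
        if pos.size > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly ascending")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "heights", hts)
        object.__setattr__(self, "prominences", prom)

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class AssignmentTable:
    """Wavenumber band -> biomolecule mapping.

    Entries are ``(band_start, band_end, substance)``; point bands have
    ``band_end == band_start``.  Published tables can place distinct
    assignments closer together than a practical matching tolerance, so
    overlap after tolerance expansion is permitted and resolved by
    nearest-band matching in :func:`assign_peaks`.
    """

    entries: tuple

    def __post_init__(self) -> None:
        for start, end, substance in self.entries:
            if end < start:
                raise ValueError(f"band end {end} before start {start}")
            if not substance:
                raise ValueError("substance names must be non-empty")

    @classmethod
    def from_csv(cls, path) -> "AssignmentTable":
        df = pd.read_csv(path)
        entries = []
        for _, row in df.iterrows():
            start = float(row["band_cm-1"])
            end = float(row["band_end_cm-1"]) if pd.notna(row.get("band_end_cm-1")) else start
            entries.append((start, end, str(row["substance"])))
        return cls(tuple(entries))

    def distance_to(self, position: float) -> list:
        """(distance, substance) for every band; 0 inside a range band."""
        out = []
        for start, end, substance in self.entries:
            if start <= position <= end:
                d = 0.0
            else:
                d = min(abs(position - start), abs(position - end))
            out.append((d, substance))
        return out


def default_assignment_table() -> AssignmentTable:
    """The packaged thyroid-tissue band assignment table."""
    with resources.as_file(
        resources.files("ramandx.data").joinpath("raman_band_assignments.csv")
    ) as path:
        return AssignmentTable.from_csv(path)


@dataclass(frozen=True)
class DifferentialPeaks:
    """Peaks of two class means split into shared and class-unique bands."""

    shared: np.ndarray
    unique_to_a: np.ndarray
    unique_to_b: np.ndarray
    match_tolerance: float


@dataclass(frozen=True)
class PeakAssignment:
    position: float
    substance: str | None  # None = unassigned


def average_sites(sample: TissueSample) -> RamanSpectrum:
    """Pointwise mean of a tissue's site spectra (the per-tumour spectrum)."""
    spectra = sample.site_spectra
    mean = np.mean([sp.intensity for sp in spectra], axis=0)
    return RamanSpectrum(sample.axis, mean, {"tissue_id": sample.tissue_id, "label": sample.label})


def class_mean_spectrum(cohort: Cohort, label: str) -> RamanSpectrum:
    """Mean over the tissue-averaged spectra carrying *label*."""
    members = cohort.with_label(label)
    if not members:
        raise ValueError(f"no samples with label {label!r}")
    averaged = [average_sites(s) for s in members]
    axis = averaged[0].axis
    for sp in averaged[1:]:
        if sp.axis != axis:
            raise ValueError("samples are on different axes")
    mean = np.mean([sp.intensity for sp in averaged], axis=0)
    return RamanSpectrum(axis, mean, {"label": label, "n_tissues": len(members)})


def _default_prominence(y: np.ndarray) -> float:
    """3x a robust noise estimate: MAD of the first difference, scaled to a
    Gaussian sd and corrected for differencing (sd of diff = sd*sqrt(2))."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    if sigma > 0:
        return 3.0 * sigma
    span = float(np.ptp(y))
    return 1e-6 * span if span > 0 else np.inf


def detect_peaks(
    spectrum: RamanSpectrum,
    min_prominence: float | None = None,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> PeakList:
    """Local maxima with prominence above threshold, >= *min_separation* apart.

    With ``min_prominence=None`` the threshold defaults to three times a
    robust noise estimate of the spectrum, so that on low-noise spectra every
    genuine band survives while dense noise wiggles do not.
    """
    y = spectrum.intensity
    if min_prominence is None:
        min_prominence = _default_prominence(y)
    distance = max(1, int(round(min_separation / spectrum.axis.step)))
    idx, props = find_peaks(y, prominence=min_prominence, distance=distance)
    return PeakList(spectrum.axis.points[idx], y[idx], props["prominences"])


def differential_peaks(
    mean_a: RamanSpectrum,
    mean_b: RamanSpectrum,
    tolerance: float = DEFAULT_MATCH_TOLERANCE,
    min_prominence: float | None = None,
) -> DifferentialPeaks:
    """Match the peaks of two class means within *tolerance* cm^-1.

    Matching is greedy on ascending position difference, each peak used at
    most once.  Shared positions are reported as the midpoint of each matched
    pair, making the operation symmetric: swapping the inputs swaps the
    unique lists and leaves the shared list unchanged.
    """
    if mean_a.axis != mean_b.axis:
        raise ValueError("class means must share one axis")
    pa = detect_peaks(mean_a, min_prominence).positions
    pb = detect_peaks(mean_b, min_prominence).positions
    pairs = sorted(
        ((abs(a - b), i, j) for i, a in enumerate(pa) for j, b in enumerate(pb)),
        key=lambda t: t[0],
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = []
    for d, i, j in pairs:
        if d > tolerance:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append(0.5 * (pa[i] + pb[j]))
    return DifferentialPeaks(
        shared=np.sort(shared),
        unique_to_a=np.asarray([p for i, p in enumerate(pa) if i not in used_a]),
        unique_to_b=np.asarray([p for j, p in enumerate(pb) if j not in used_b]),
        match_tolerance=tolerance,
    )


def assign_peaks(
    peaks: PeakList,
    table: AssignmentTable | None = None,
    tolerance: float = DEFAULT_MATCH_TOLERANCE,
) -> list:
    """Annotate each detected peak with the nearest band within *tolerance*.

    Range bands match at distance zero anywhere inside the range; peaks
    farther than *tolerance* from every band come back unassigned.
    """
    if table is None:
        table = default_assignment_table()
    out = []
    for p in peaks.positions:
        dists = table.distance_to(float(p))
        d, substance = min(dists, key=lambda t: t[0])
        out.append(PeakAssignment(float(p), substance if d <= tolerance else None))
    return out
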