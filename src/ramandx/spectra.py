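"""Core containers for Raman spectra, tissue samples and cohorts, plus text I/O.

A Raman spectrum is intensity sampled on a uniform wavenumber grid (cm^-1).
Every preprocessing operator maps :class:`RamanSpectrum` to itself, so the
container is deliberately small: an axis, an intensity vector, and free-form
acquisition metadata (tissue id, scan site, laser line, power, exposure).

Spectra travel on disk as two-column CSV (``wavenumber_cm-1,intensity``);
cohorts as a manifest TSV (``tissue_id, label, site, spectrum_path``) pointing
at one spectrum file per scan site.  A minimal JCAMP-DX reader is provided for
instrument exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberAxis",
    "RamanSpectrum",
    "TissueSample",
    "Cohort",
    "make_axis",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcamp",
    "load_cohort",
    "save_cohort",
    "BENIGN",
    "MALIGNANT",
    "LABELS",
]

#: Canonical class labels, in the row/column order used throughout.
BENIGN = "benign"
MALIGNANT = "malignant"
LABELS = (BENIGN, MALIGNANT)

_SPECTRUM_HEADER = ("wavenumber_cm-1", "intensity")
_UNIFORMITY_RTOL = 1e-9


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly ascending, uniformly spaced wavenumber grid in cm^-1."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("axis needs at least two points")
        steps = np.diff(pts)
        if np.any(steps <= 0):
            raise ValueError("axis must be strictly ascending")
        step = steps[0]
        if np.any(np.abs(steps - step) > _UNIFORMITY_RTOL * max(abs(step), 1.0)):
            raise ValueError("axis spacing must be uniform")
        object.__setattr__(self, "points", pts)

    @property
    def start(self) -> float:
        return float(self.points[0])

    @property
    def stop(self) -> float:
        return float(self.points[-1])

    @property
    def step(self) -> float:
        return float(self.points[1] - self.points[0])

    def __len__(self) -> int:
        return self.points.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.points.shape == other.points.shape and bool(
            np.allclose(self.points, other.points, rtol=0, atol=1e-9 * max(abs(self.step), 1.0))
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.points.size, self.start, self.stop))

    def shifted(self, delta: float) -> "WavenumberAxis":
        """Rigidly translated copy (used by wavenumber calibration)."""
        return WavenumberAxis(self.points + float(delta))

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.stop

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to *wavenumber*."""
        return int(np.argmin(np.abs(self.points - wavenumber)))


def make_axis(start: float, stop: float, step: float) -> WavenumberAxis:
    """Build the inclusive uniform grid from *start* to *stop* with spacing *step*.

    Raises ``ValueError`` for an inverted range or non-positive step.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if start >= stop:
        raise ValueError(f"inverted range: start={start} >= stop={stop}")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return WavenumberAxis(start + step * np.arange(n))


@dataclass
class RamanSpectrum:
    """Intensity per wavenumber with acquisition metadata.

    Intensities must be finite and match the axis length; negativity is not
    enforced because baseline-subtracted spectra may dip below zero mid-chain.
    """

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if inten.shape != (len(self.axis),) :
            raise ValueError(
                f"intensity length {inten.shape} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        self.intensity = inten

    def with_intensity(self, intensity: np.ndarray) -> "RamanSpectrum":
        return RamanSpectrum(self.axis, intensity, dict(self.meta))

    def with_axis(self, axis: WavenumberAxis) -> "RamanSpectrum":
        return RamanSpectrum(axis, self.intensity.copy(), dict(self.meta))

    def area(self) -> float:
        """Trapezoidal integral of intensity over the axis."""
        return float(np.trapezoid(self.intensity, self.axis.points))


@dataclass
class TissueSample:
    """One labelled tissue specimen with its per-site spectra.

    This is the unit held out in cross-validation: all scan sites of a tissue
    leave the training set together.
    """

    tissue_id: str
    label: str
    site_spectra: list

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.site_spectra:
            raise ValueError("a tissue needs at least one site spectrum")
        axis = self.site_spectra[0].axis
        for sp in self.site_spectra[1:]:
            if sp.axis != axis:
                raise ValueError(f"site spectra of {self.tissue_id} are on different axes")

    @property
    def axis(self) -> WavenumberAxis:
        return self.site_spectra[0].axis


@dataclass
class Cohort:
    """A collection of labelled tissues with unique ids."""

    samples: list

    def __post_init__(self) -> None:
        ids = [s.tissue_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("tissue_ids must be unique")

    def __len__(self) -> int:
        return len(self.samples)

    def with_label(self, label: str) -> list:
        return [s for s in self.samples if s.label == label]

    def labels(self) -> list:
        return [s.label for s in self.samples]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_spectrum_csv(spectrum: RamanSpectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {_SPECTRUM_HEADER[0]: spectrum.axis.points, _SPECTRUM_HEADER[1]: spectrum.intensity}
    )
    df.to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, meta: Mapping | None = None) -> RamanSpectrum:
    df = pd.read_csv(path)
    missing = [c for c in _SPECTRUM_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected {_SPECTRUM_HEADER}")
    return RamanSpectrum(
        WavenumberAxis(df[_SPECTRUM_HEADER[0]].to_numpy(float)),
        df[_SPECTRUM_HEADER[1]].to_numpy(float),
        dict(meta or {}),
    )


def read_jcamp(path: str | Path) -> RamanSpectrum:
    """Read a simple single-block JCAMP-DX file (XYDATA=(X++(Y..Y)) or XYPOINTS).

    Supports the fixed-point tabular layouts that Raman instrument software
    exports; compressed (DIF/DUP/SQZ) encodings are out of scope.
    """
    text = Path(path).read_text()
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None
    for raw in text.splitlines():
        line = raw.split("$$", 1)[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("XYDATA", "XYPOINTS"):
                mode = key
            elif key == "END":
                break
            else:
                fields[key] = value
        elif mode:
            data_lines.append(line)
    if mode is None:
        raise ValueError(f"{path}: no XYDATA/XYPOINTS block found")
    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    if mode == "XYPOINTS":
        for line in data_lines:
            for pair in line.replace(";", " ").split():
                x, _, y = pair.partition(",")
                xs.append(float(x) * xfactor)
                ys.append(float(y) * yfactor)
    else:  # X++(Y..Y): first token per line is X of the first Y
        deltax = fields.get("DELTAX")
        values = [np.fromstring(line.replace(",", " "), sep=" ") for line in data_lines]
        if deltax is not None:
            dx = float(deltax)
        else:
            firsts = [v[0] for v in values]
            counts = [v.size - 1 for v in values]
            if len(values) > 1:
                dx = (firsts[1] - firsts[0]) / counts[0]
            else:
                last = float(fields["LASTX"]) / xfactor
                dx = (last - firsts[0]) / max(counts[0] - 1, 1)
        for v in values:
            x0 = v[0]
            for j, y in enumerate(v[1:]):
                xs.append((x0 + j * dx) * xfactor)
                ys.append(float(y) * yfactor)
    order = np.argsort(xs)
    meta = {"source": str(path), "title": fields.get("TITLE", "")}
    return RamanSpectrum(WavenumberAxis(np.asarray(xs)[order]), np.asarray(ys)[order], meta)


def save_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write one spectrum CSV per (tissue, site) plus a manifest TSV.

    Returns the manifest path. Layout: ``<dir>/<tissue_id>_site<k>.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in cohort.samples:
        for sp in sample.site_spectra:
            site = int(sp.meta.get("site", 0))
            fname = f"{sample.tissue_id}_site{site}.csv"
            write_spectrum_csv(sp, directory / fname)
            rows.append(
                {"tissue_id": sample.tissue_id, "label": sample.label,
                 "site": site, "spectrum_path": fname}
            )
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a manifest TSV; spectrum paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    required = {"tissue_id", "label", "site", "spectrum_path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    samples = []
    for tissue_id, group in df.groupby("tissue_id", sort=False):
        labels = set(group["label"])
        if len(labels) != 1:
            raise ValueError(f"tissue {tissue_id} has conflicting labels {labels}")
        spectra = []
        for _, row in group.sort_values("site").iterrows():
            path = Path(row["spectrum_path"])
            if not path.is_absolute():
                path = manifest_path.parent / path
            if not path.exists():
                raise FileNotFoundError(f"spectrum file not found: {path}")
            spectra.append(
                read_spectrum_csv(path, {"tissue_id": str(tissue_id), "site": int(row["site"])})
            )
        samples.append(TissueSample(str(tissue_id), str(labels.pop()), spectra))
    return Cohort(samples)
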