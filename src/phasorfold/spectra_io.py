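"""Domain containers and plain-text I/O for spectral series and kinetic traces.

On-disk layout is long/tidy CSV — one row per wavelength per spectrum — with
the fixed header ``series_id,axis_type,axis_value,wavelength_nm,intensity_au``.
Kinetic traces use ``time_min,intensity_au``. Fit results are JSON documents
carrying a ``schema_version`` field. Axis units are fixed by the axis kind
(molar for chemical denaturant, bar for pressure); there is no unit
autodetection, because silent unit errors dominate this domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    IntegrityError,
    ParseError,
    ReportError,
    ValidationError,
)

SCHEMA_VERSION = "1.0"
AXIS_KINDS = ("denaturant_M", "pressure_bar")

SERIES_COLUMNS = ["series_id", "axis_type", "axis_value", "wavelength_nm", "intensity_au"]
TRACE_COLUMNS = ["time_min", "intensity_au"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class EmissionSpectrum:
    """A single emission scan: wavelength grid (nm) plus intensities (a.u.).

    Wavelengths must be strictly increasing with at least two samples;
    intensities are finite, non-negative, and match the grid length.
    """

    wavelengths_nm: np.ndarray
    intensities_au: np.ndarray
    excitation_nm: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = _as_float_array(self.wavelengths_nm, "wavelengths_nm")
        self.intensities_au = _as_float_array(self.intensities_au, "intensities_au")
        if self.wavelengths_nm.size < 2:
            raise ValidationError("spectrum needs at least 2 wavelength samples")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.intensities_au.size != self.wavelengths_nm.size:
            raise ValidationError("intensities and wavelengths differ in length")
        if np.any(self.intensities_au < 0):
            raise ValidationError("intensities must be non-negative")

    def __eq__(self, other) -> bool:
        if not isinstance(other, EmissionSpectrum):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.intensities_au, other.intensities_au)
            and self.excitation_nm == other.excitation_nm
            and self.label == other.label
        )


@dataclass
class SpectralSeries:
    """Ordered spectra along one perturbation axis (denaturant M or pressure bar)."""

    axis_kind: str
    axis_values: np.ndarray
    spectra: list[EmissionSpectrum]
    shared_grid: bool = True

    def __post_init__(self) -> None:
        if self.axis_kind not in AXIS_KINDS:
            raise ValidationError(
                f"axis_kind must be one of {AXIS_KINDS}, got {self.axis_kind!r}"
            )
        self.axis_values = _as_float_array(self.axis_values, "axis_values")
        if len(self.spectra) != self.axis_values.size:
            raise ValidationError("axis_values and spectra differ in length")
        if not np.all(np.diff(self.axis_values) > 0):
            raise ValidationError("axis_values must be strictly increasing")
        if self.shared_grid and len(self.spectra) > 1:
            ref = self.spectra[0].wavelengths_nm
            for sp in self.spectra[1:]:
                if not np.array_equal(sp.wavelengths_nm, ref):
                    raise ValidationError("shared_grid set but wavelength grids differ")

    def __len__(self) -> int:
        return len(self.spectra)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectralSeries):
            return NotImplemented
        return (
            self.axis_kind == other.axis_kind
            and np.array_equal(self.axis_values, other.axis_values)
            and self.spectra == other.spectra
        )


@dataclass
class KineticTrace:
    """Thioflavin-T time course: time (min) vs fluorescence intensity (a.u.)."""

    times_min: np.ndarray
    intensities_au: np.ndarray
    temperature_K: float = 310.15

    def __post_init__(self) -> None:
        self.times_min = _as_float_array(self.times_min, "times_min")
        self.intensities_au = _as_float_array(self.intensities_au, "intensities_au")
        if self.times_min.size != self.intensities_au.size:
            raise ValidationError("times and intensities differ in length")
        if self.times_min.size and self.times_min[0] < 0:
            raise ValidationError("first time point must be >= 0")
        if np.any(np.diff(self.times_min) < 0):
            raise ValidationError("times must be non-decreasing")

    def __len__(self) -> int:
        return self.times_min.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, KineticTrace):
            return NotImplemented
        return (
            np.array_equal(self.times_min, other.times_min)
            and np.array_equal(self.intensities_au, other.intensities_au)
            and self.temperature_K == other.temperature_K
        )


# --------------------------------------------------------------------------
# CSV reading / writing
# --------------------------------------------------------------------------

def _read_numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna() | df[column].isna()
    if bad.any():
        # +2: one for the header line, one for 0-based indexing
        row = int(bad.idxmax()) + 2
        raise ParseError(
            f"{path}: non-numeric value {df[column].iloc[bad.idxmax()]!r} "
            f"in column {column!r} at file row {row}"
        )
    return converted.to_numpy(dtype=float)


def read_spectral_series(path) -> SpectralSeries:
    """Read a long-format spectral-series CSV into a validated SpectralSeries.

    Spectra are grouped by ``axis_value`` and sorted ascending; wavelengths
    within each spectrum are sorted. Raises FormatError for missing columns,
    ParseError (naming the row) for non-numeric cells and IntegrityError for
    duplicate (axis_value, wavelength) pairs.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    series_ids = df["series_id"].unique()
    if len(series_ids) != 1:
        raise IntegrityError(
            f"{path}: expected exactly one series_id, found {sorted(series_ids)}"
        )
    axis_types = df["axis_type"].unique()
    if len(axis_types) != 1:
        raise IntegrityError(f"{path}: mixed axis_type values {sorted(axis_types)}")
    axis_kind = str(axis_types[0])
    if axis_kind not in AXIS_KINDS:
        raise FormatError(
            f"{path}: unknown axis_type {axis_kind!r}; expected one of {AXIS_KINDS}"
        )

    axis = _read_numeric(df, "axis_value", path)
    wl = _read_numeric(df, "wavelength_nm", path)
    inten = _read_numeric(df, "intensity_au", path)

    work = pd.DataFrame({"axis": axis, "wl": wl, "inten": inten})
    if work.duplicated(subset=["axis", "wl"]).any():
        dup = work[work.duplicated(subset=["axis", "wl"])].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate (axis_value={dup.axis}, wavelength_nm={dup.wl}) record"
        )

    spectra: list[EmissionSpectrum] = []
    axis_values: list[float] = []
    for ax, grp in work.groupby("axis", sort=True):
        grp = grp.sort_values("wl")
        spectra.append(
            EmissionSpectrum(
                wavelengths_nm=grp["wl"].to_numpy(),
                intensities_au=grp["inten"].to_numpy(),
                label=f"{series_ids[0]}@{ax:g}",
            )
        )
        axis_values.append(float(ax))

    grids = {tuple(sp.wavelengths_nm) for sp in spectra}
    return SpectralSeries(
        axis_kind=axis_kind,
        axis_values=np.asarray(axis_values),
        spectra=spectra,
        shared_grid=len(grids) == 1,
    )


def write_spectral_series(series: SpectralSeries, path, series_id: str = "series") -> None:
    """Write a SpectralSeries as long-format CSV (the reader's inverse)."""
    rows = []
    for ax, sp in zip(series.axis_values, series.spectra):
        for w, i in zip(sp.wavelengths_nm, sp.intensities_au):
            rows.append((series_id, series.axis_kind, ax, w, i))
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def read_kinetic_trace(path, temperature_K: float = 310.15) -> KineticTrace:
    """Read a two-column kinetic-trace CSV (time_min, intensity_au)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    t = _read_numeric(df, "time_min", path)
    y = _read_numeric(df, "intensity_au", path)
    order = np.argsort(t, kind="stable")
    return KineticTrace(times_min=t[order], intensities_au=y[order],
                        temperature_K=temperature_K)


def write_kinetic_trace(trace: KineticTrace, path) -> None:
    pd.DataFrame(
        {"time_min": trace.times_min, "intensity_au": trace.intensities_au}
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Fit reports (JSON)
# --------------------------------------------------------------------------

def write_fit_report(fit, path) -> None:
    """Serialize a converged ThermoFit or KineticFit to a JSON report.

    The report embeds the schema version and the package version so a result
    file is interpretable on its own. Raises ReportError for non-converged fits.
    """
    from . import __version__  # local import avoids a cycle at module load

    if not getattr(fit, "converged", False):
        raise ReportError("refusing to write a report for a non-converged fit")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "tool": {"name": "phasorfold", "version": __version__},
        "fit": fit.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_fit_report(path):
    """Load a JSON fit report back into the fit object it was written from."""
    doc = json.loads(Path(path).read_text())
    if "fit" not in doc or "schema_version" not in doc:
        raise FormatError(f"{path}: not a phasorfold fit report")
    payload = doc["fit"]
    kind = payload.get("kind")
    if kind in ("chemical", "pressure"):
        from .equilibrium_thermo import ThermoFit

        return ThermoFit.from_dict(payload)
    if kind == "kinetic":
        from .aggregation_kinetics import KineticFit

        return KineticFit.from_dict(payload)
    raise FormatError(f"{path}: unknown fit kind {kind!r}")
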