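"""Scalar observables of emission spectra.

Three readouts drive the downstream analysis:

* the center of spectral mass (CSM), the intensity-weighted mean spectral
  position — reported in wavenumber (cm^-1) by default, where a red shift
  *lowers* the value, with an nm-scale option;
* the fraction unfolded, the CSM series normalized between folded and
  unfolded endpoint values; and
* the integrated light-scattering signal over a wavelength window.

Values of the fraction unfolded outside [0, 1] are preserved (and flagged
with a warning) rather than clipped: non-monotone CSM series are exactly the
signature of hidden states that the phasor module is designed to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateEndpointsError,
    EmptyWindowError,
    OutOfRangeAlphaWarning,
    UndefinedObservableError,
)
from .spectra_io import EmissionSpectrum, SpectralSeries

NM_TO_WAVENUMBER = 1.0e7  # nu[cm^-1] = 1e7 / lambda[nm]


@dataclass
class UnfoldingCurve:
    """CSM and fraction-unfolded series along one perturbation axis."""

    axis_kind: str
    axis_values: np.ndarray
    csm_values: np.ndarray
    alpha: np.ndarray
    v_i: float
    v_f: float
    scale: str = "wavenumber"


def center_of_spectral_mass(spectrum: EmissionSpectrum, scale: str = "wavenumber") -> float:
    """Intensity-weighted mean spectral position of one emission scan.

    ``scale="wavenumber"`` averages nu_k = 1e7/lambda_k (cm^-1, the default,
    matching how red shifts are conventionally reported); ``scale="nm"``
    averages the wavelength grid directly. The two are *not* equivalent —
    the weighted mean does not commute with the 1/lambda map.
    """
    total = float(np.sum(spectrum.intensities_au))
    if total <= 0.0:
        raise UndefinedObservableError("center of mass undefined for zero spectrum")
    if scale == "wavenumber":
        coord = NM_TO_WAVENUMBER / spectrum.wavelengths_nm
    elif scale == "nm":
        coord = spectrum.wavelengths_nm
    else:
        raise ValueError(f"scale must be 'wavenumber' or 'nm', got {scale!r}")
    return float(np.sum(coord * spectrum.intensities_au) / total)


def fraction_unfolded(csm_values, v_i: float, v_f: float) -> np.ndarray:
    """Normalize a CSM series between folded (v_i) and unfolded (v_f) endpoints.

    alpha_k = (v_k - v_i) / (v_f - v_i). Endpoints map to exactly 0 and 1.
    Values outside [0, 1] are kept and flagged with OutOfRangeAlphaWarning.
    """
    csm = np.atleast_1d(np.asarray(csm_values, dtype=float))
    if v_f == v_i:
        raise DegenerateEndpointsError("v_f == v_i: cannot normalize CSM series")
    alpha = (csm - v_i) / (v_f - v_i)
    if np.any((alpha < 0.0) | (alpha > 1.0)):
        out = alpha[(alpha < 0.0) | (alpha > 1.0)]
        warnings.warn(
            f"{out.size} fraction-unfolded value(s) outside [0, 1] "
            f"(extrema {out.min():.4g}, {out.max():.4g}); kept unclipped",
            OutOfRangeAlphaWarning,
            stacklevel=2,
        )
    return alpha


def light_scattering_area(spectrum: EmissionSpectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of intensity over a wavelength window (a.u. * nm).

    Window edges falling between grid samples contribute linearly
    interpolated boundary points.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise EmptyWindowError(f"empty or inverted window ({lo}, {hi})")
    wl, inten = spectrum.wavelengths_nm, spectrum.intensities_au
    if hi < wl[0] or lo > wl[-1]:
        raise EmptyWindowError(f"window ({lo}, {hi}) outside grid [{wl[0]}, {wl[-1]}]")
    lo, hi = max(lo, wl[0]), min(hi, wl[-1])
    mask = (wl >= lo) & (wl <= hi)
    x = wl[mask]
    y = inten[mask]
    if lo < (x[0] if x.size else hi):
        x = np.insert(x, 0, lo)
        y = np.insert(y, 0, np.interp(lo, wl, inten))
    if hi > (x[-1] if x.size else lo):
        x = np.append(x, hi)
        y = np.append(y, np.interp(hi, wl, inten))
    if x.size < 2:
        raise EmptyWindowError(f"window ({lo}, {hi}) contains no integrable span")
    return float(np.trapezoid(y, x))


def unfolding_curve(
    series: SpectralSeries,
    scale: str = "wavenumber",
    v_i: float | None = None,
    v_f: float | None = None,
) -> UnfoldingCurve:
    """Compute CSM per spectrum and normalize to fraction unfolded.

    Endpoints default to the first/last spectra of the series; explicit
    folded/unfolded anchor values may be supplied instead (e.g. when the
    last recorded condition is not fully unfolded, or is contaminated by
    scattering).
    """
    csm = np.array([center_of_spectral_mass(sp, scale=scale) for sp in series.spectra])
    vi = float(csm[0]) if v_i is None else float(v_i)
    vf = float(csm[-1]) if v_f is None else float(v_f)
    alpha = fraction_unfolded(csm, vi, vf)
    return UnfoldingCurve(
        axis_kind=series.axis_kind,
        axis_values=series.axis_values.copy(),
        csm_values=csm,
        alpha=alpha,
        v_i=vi,
        v_f=vf,
        scale=scale,
    )
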