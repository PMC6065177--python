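"""Spectral phasor transform and model-free diagnostics of spectral series.

The phasor of an emission spectrum is the first-harmonic discrete Fourier
coefficient of the intensity profile, normalized by total intensity:

    G = sum_k I_k cos(2*pi*n*k/K) / sum_k I_k
    S = sum_k I_k sin(2*pi*n*k/K) / sum_k I_k

with k = 0..K-1 the channel index across the recorded interval and n the
harmonic (default 1). Because the phasor of a sum of spectra is the
intensity-weighted mean of the component phasors, a strictly two-state
series traces a straight segment between the folded and unfolded phasors;
any population of a third species pulls points off that segment, and a
scattering-dominated spectrum (aggregation) turns the trajectory around.
These diagnostics are model independent: no fit to a folding model is
involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateLineError,
    InsufficientDataError,
    UndefinedPhasorError,
)
from .spectra_io import EmissionSpectrum, SpectralSeries

_UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class PhasorPoint:
    """One (G, S) phasor coordinate at harmonic ``harmonic_n``."""

    G: float
    S: float
    harmonic_n: int = 1

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.S])


@dataclass
class PhasorTrajectory:
    """Ordered phasor points of a series with linearity diagnostics.

    ``deviations`` holds each point's perpendicular distance to the line
    through the endpoint anchors (the "line of linear combination" of the
    folded and unfolded phasors).
    """

    points: np.ndarray            # (n, 2) array of (G, S)
    axis_values: np.ndarray
    harmonic_n: int
    anchor_f: PhasorPoint
    anchor_u: PhasorPoint
    deviations: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.deviations = _point_line_distances(
            self.points, self.anchor_f.as_array(), self.anchor_u.as_array()
        )

    def __len__(self) -> int:
        return self.points.shape[0]


def _point_line_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point to the line through a and b.

    Coincident anchors degrade gracefully to the distance to the single
    anchor point (so a series of identical spectra reports zero deviation).
    """
    ab = b - a
    norm = np.hypot(*ab)
    if norm == 0.0:
        return np.hypot(points[:, 0] - a[0], points[:, 1] - a[1])
    cross = (points[:, 0] - a[0]) * ab[1] - (points[:, 1] - a[1]) * ab[0]
    return np.abs(cross) / norm


def _uniform_channels(spectrum: EmissionSpectrum) -> np.ndarray:
    """Intensities on a uniform wavelength grid, resampling if needed.

    Non-uniform grids are linearly interpolated onto a uniform grid spanning
    the same interval at the finest spacing present.
    """
    wl = spectrum.wavelengths_nm
    steps = np.diff(wl)
    if np.allclose(steps, steps[0], rtol=_UNIFORM_RTOL, atol=0.0):
        return spectrum.intensities_au
    step = steps.min()
    n = int(round((wl[-1] - wl[0]) / step)) + 1
    grid = np.linspace(wl[0], wl[-1], n)
    return np.interp(grid, wl, spectrum.intensities_au)


def phasor_transform(spectrum: EmissionSpectrum, n: int = 1) -> PhasorPoint:
    """First-harmonic (or n-th) spectral phasor of one emission spectrum.

    The recorded interval maps onto exactly one period: channel k of K
    carries phase 2*pi*n*k/K, zero-based. Raises UndefinedPhasorError for an
    all-zero spectrum.
    """
    if n < 1:
        raise ValueError("harmonic n must be a positive integer")
    intensities = _uniform_channels(spectrum)
    total = float(np.sum(intensities))
    if total <= 0.0:
        raise UndefinedPhasorError("phasor undefined for zero total intensity")
    k = np.arange(intensities.size)
    phase = 2.0 * np.pi * n * k / intensities.size
    g = float(np.sum(intensities * np.cos(phase)) / total)
    s = float(np.sum(intensities * np.sin(phase)) / total)
    return PhasorPoint(G=g, S=s, harmonic_n=n)


def trajectory(
    series: SpectralSeries,
    n: int = 1,
    anchor_f: PhasorPoint | None = None,
    anchor_u: PhasorPoint | None = None,
) -> PhasorTrajectory:
    """Phasor trajectory of a spectral series.

    Endpoint anchors default to the first and last points of the series;
    explicit folded/unfolded anchors should be supplied when an endpoint
    spectrum is not a valid pure-state reference (e.g. contaminated by the
    scattering of an aggregated sample).
    """
    pts = []
    for ax, sp in zip(series.axis_values, series.spectra):
        try:
            pts.append(phasor_transform(sp, n=n).as_array())
        except UndefinedPhasorError as err:
            raise UndefinedPhasorError(
                f"at axis value {ax:g} ({series.axis_kind}): {err}"
            ) from err
    points = np.vstack(pts)
    af = anchor_f if anchor_f is not None else PhasorPoint(*points[0], harmonic_n=n)
    au = anchor_u if anchor_u is not None else PhasorPoint(*points[-1], harmonic_n=n)
    return PhasorTrajectory(
        points=points,
        axis_values=series.axis_values.copy(),
        harmonic_n=n,
        anchor_f=af,
        anchor_u=au,
    )


def collinearity_statistic(traj: PhasorTrajectory) -> float:
    """Maximum perpendicular deviation from the endpoint line, normalized.

    Deviations are divided by the anchor separation, so the statistic is
    invariant to the overall spread of the trajectory. Zero means perfectly
    two-state; a strictly positive value reports population of species off
    the folded-unfolded linear-combination line.
    """
    if len(traj) < 3:
        raise InsufficientDataError("collinearity needs at least 3 points")
    sep = float(np.hypot(*(traj.anchor_u.as_array() - traj.anchor_f.as_array())))
    if sep == 0.0:
        raise DegenerateLineError("endpoint anchors coincide; no reference line")
    return float(traj.deviations.max() / sep)


def detect_inflection(
    traj: PhasorTrajectory,
    angle_threshold_deg: float = 90.0,
    min_segment_frac: float = 0.05,
) -> int | None:
    """Index of the first sharp turn of the trajectory, or None.

    At each interior vertex the turning angle between the incoming and the
    outgoing segment is evaluated; the first vertex whose angle exceeds the
    threshold (default 90 degrees) is returned. Segments shorter than
    ``min_segment_frac`` of the trajectory's bounding-box diagonal are
    ignored, so that noise jitter of nearly coincident points (a stalled
    trajectory end) cannot mimic a turn. A sharp turn signals departure
    from the folding path toward scattering-dominated spectra, i.e. the
    onset of aggregation.
    """
    if len(traj) < 4:
        raise InsufficientDataError("inflection detection needs at least 4 points")
    pts = traj.points
    span = pts.max(axis=0) - pts.min(axis=0)
    scale = float(np.hypot(*span))
    if scale == 0.0:
        return None
    min_len = min_segment_frac * scale
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cos_thresh = np.cos(np.deg2rad(angle_threshold_deg))
    for j in range(1, len(traj) - 1):
        a, b = seg[j - 1], seg[j]
        if seg_len[j - 1] < min_len or seg_len[j] < min_len:
            continue
        cos_angle = float(np.dot(a, b) / (seg_len[j - 1] * seg_len[j]))
        if cos_angle < cos_thresh:
            return j
    return None
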