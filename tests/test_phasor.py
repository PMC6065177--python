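"""Spectral phasor transform, linearity diagnostics and inflection detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phasorfold as pf
from phasorfold.exceptions import (
    DegenerateLineError,
    InsufficientDataError,
    UndefinedPhasorError,
)
from phasorfold.synthetic_data import ScatteringSpec


def dft_oracle(intensities, n=1):
    """Brute-force discrete-Fourier phasor: sum over explicit cos/sin terms."""
    total = sum(intensities)
    K = len(intensities)
    g = sum(I * np.cos(2 * np.pi * n * k / K) for k, I in enumerate(intensities)) / total
    s = sum(I * np.sin(2 * np.pi * n * k / K) for k, I in enumerate(intensities)) / total
    return g, s


class TestPhasorTransform:
    def test_delta_at_first_channel(self):
        wl = np.arange(290.0, 298.0)
        inten = np.zeros(8)
        inten[0] = 5.0
        p = pf.phasor_transform(pf.EmissionSpectrum(wl, inten))
        assert (p.G, p.S) == pytest.approx((1.0, 0.0), abs=1e-14)

    def test_delta_at_quarter_period(self):
        wl = np.arange(290.0, 298.0)
        inten = np.zeros(8)
        inten[2] = 1.0          # k = K/4 of K = 8
        p = pf.phasor_transform(pf.EmissionSpectrum(wl, inten))
        assert (p.G, p.S) == pytest.approx((0.0, 1.0), abs=1e-14)

    def test_uniform_spectrum_maps_to_origin(self, grid_nm):
        p = pf.phasor_transform(pf.EmissionSpectrum(grid_nm, np.ones_like(grid_nm)))
        assert (p.G, p.S) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_gaussian_band_matches_oracle(self, gaussian_spectrum):
        p = pf.phasor_transform(gaussian_spectrum)
        g, s = dft_oracle(gaussian_spectrum.intensities_au)
        assert p.G == pytest.approx(g, abs=1e-12)
        assert p.S == pytest.approx(s, abs=1e-12)

    def test_second_harmonic_matches_oracle(self, gaussian_spectrum):
        p = pf.phasor_transform(gaussian_spectrum, n=2)
        g, s = dft_oracle(gaussian_spectrum.intensities_au, n=2)
        assert (p.G, p.S) == pytest.approx((g, s), abs=1e-12)

    def test_zero_spectrum_undefined(self, grid_nm):
        with pytest.raises(UndefinedPhasorError):
            pf.phasor_transform(pf.EmissionSpectrum(grid_nm, np.zeros_like(grid_nm)))

    def test_nonuniform_grid_resampled(self):
        # same band sampled uniformly vs with a missing channel: close phasors
        wl = np.arange(290.0, 401.0, 1.0)
        inten = np.exp(-0.5 * ((wl - 330.0) / 15.0) ** 2)
        keep = np.ones(wl.size, bool)
        keep[40] = False
        p_full = pf.phasor_transform(pf.EmissionSpectrum(wl, inten))
        p_gap = pf.phasor_transform(pf.EmissionSpectrum(wl[keep], inten[keep]))
        assert p_gap.G == pytest.approx(p_full.G, abs=1e-4)
        assert p_gap.S == pytest.approx(p_full.S, abs=1e-4)

    @given(seed=st.integers(0, 500))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_phasor_inside_unit_disk_and_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.integers(4, 200)
        inten = rng.random(K)
        wl = np.arange(290.0, 290.0 + K)
        p = pf.phasor_transform(pf.EmissionSpectrum(wl, inten))
        assert np.hypot(p.G, p.S) <= 1.0 + 1e-12
        q = pf.phasor_transform(pf.EmissionSpectrum(wl, inten * 37.5))
        assert (q.G, q.S) == pytest.approx((p.G, p.S), abs=1e-12)

    @given(w=st.floats(0.0, 1.0), seed=st.integers(0, 100))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_mixture_phasor_on_segment(self, w, seed):
        rng = np.random.default_rng(seed)
        wl = np.arange(290.0, 401.0)
        A, B = rng.random(wl.size), rng.random(wl.size)
        pa = pf.phasor_transform(pf.EmissionSpectrum(wl, A)).as_array()
        pb = pf.phasor_transform(pf.EmissionSpectrum(wl, B)).as_array()
        pm = pf.phasor_transform(pf.EmissionSpectrum(wl, w * A + (1 - w) * B)).as_array()
        ab = pb - pa
        denom = float(ab @ ab)
        if denom == 0.0:
            return
        t = float((pm - pa) @ ab) / denom
        perp = np.hypot(*(pm - (pa + t * ab)))
        assert perp < 1e-12
        assert -1e-9 <= t <= 1 + 1e-9


class TestTrajectory:
    def test_two_state_series_collinear(self, chemical_config):
        traj = pf.trajectory(pf.simulate_titration(chemical_config))
        assert traj.deviations.max() < 1e-10
        assert pf.collinearity_statistic(traj) < 1e-10

    def test_three_state_series_deviates(self, anchors):
        cfg = pf.three_state_chemical(seed=4)
        af = pf.phasor_transform(pf.pure_state_spectrum(cfg, 0))
        au = pf.phasor_transform(pf.pure_state_spectrum(cfg, 2))
        traj = pf.trajectory(pf.simulate_titration(cfg), anchor_f=af, anchor_u=au)
        assert pf.collinearity_statistic(traj) > 1e-3

    def test_identical_spectra_coincide(self, grid_nm):
        sp_int = np.exp(-0.5 * ((grid_nm - 320.0) / 10.0) ** 2)
        spectra = [pf.EmissionSpectrum(grid_nm, sp_int.copy()) for _ in range(4)]
        series = pf.SpectralSeries("denaturant_M", [0.0, 1.0, 2.0, 3.0], spectra)
        traj = pf.trajectory(series)
        assert np.allclose(traj.deviations, 0.0)
        with pytest.raises(DegenerateLineError):
            pf.collinearity_statistic(traj)


class TestDetectInflection:
    def test_monotone_two_state_has_none(self, chemical_config):
        traj = pf.trajectory(pf.simulate_titration(chemical_config))
        assert pf.detect_inflection(traj) is None

    def test_scattering_onset_triggers_at_first_post_onset_point(self):
        axis = np.arange(0.0, 3601.0, 600.0)
        cfg = pf.two_state_pressure(
            64.4, 2900.0, axis_values=axis, seed=5, noise_cv=0.01,
            scattering=ScatteringSpec(onset_bar=2700.0),
        )
        traj = pf.trajectory(pf.simulate_titration(cfg))
        assert pf.detect_inflection(traj) == int(np.argmax(axis >= 2700.0))

    def test_constructed_reversal_at_midpoint(self):
        pts = np.array([[0.0, 0.0], [0.2, 0.0], [0.4, 0.0], [0.2, 0.0], [0.0, 0.0]])
        traj = pf.PhasorTrajectory(
            points=pts,
            axis_values=np.arange(5.0),
            harmonic_n=1,
            anchor_f=pf.PhasorPoint(0.0, 0.0),
            anchor_u=pf.PhasorPoint(0.4, 0.0),
        )
        assert pf.detect_inflection(traj) == 2

    def test_too_few_points(self):
        traj = pf.PhasorTrajectory(
            points=np.array([[0.0, 0.0], [0.1, 0.0], [0.2, 0.0]]),
            axis_values=np.arange(3.0),
            harmonic_n=1,
            anchor_f=pf.PhasorPoint(0.0, 0.0),
            anchor_u=pf.PhasorPoint(0.2, 0.0),
        )
        with pytest.raises(InsufficientDataError):
            pf.detect_inflection(traj)
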