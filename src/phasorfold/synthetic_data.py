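"""Synthetic emission-spectrum titrations and ThT kinetic traces.

Raw fluorescence data of the kind this package analyzes (equilibrium
titrations of a Trp/Tyr-probed protein domain, pressure series with an
aggregation scattering artifact, thioflavin-T aggregation time courses) are
rarely deposited; this module generates series with the statistical
structure the downstream analysis assumes, so every stage is testable
end to end.

Model: each conformational state contributes a basis spectrum (a sum of
Gaussian bands, Gaussian in wavenumber space by default, as emission bands
are); state populations follow Boltzmann weights of linear free energies
G_i(x) = G0_i - s_i * x along the perturbation axis, which for two states
reduces to the standard two-state equilibrium alpha = Keq/(1+Keq) with
Keq = exp(-(DeltaG0 - m x)/RT). State basis spectra are normalized to equal
integrated intensity by default, which makes the center of spectral mass of
a mixture exactly affine in the population fraction — the idealization
under which CSM normalization recovers the true fraction unfolded.

Pressure series can add a scattering spike: the long-wavelength tail of a
band centered at the excitation wavelength, with relative amplitude growing
quadratically with pressure above an aggregation onset — emulating the
abrupt rise of scattering counts near the excitation line when a sample
aggregates under pressure.

Noise is multiplicative Gaussian (coefficient of variation of intensity)
for spectra and additive Gaussian for kinetic traces; both are fully
deterministic given the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation_kinetics import KineticParams, model_F
from .equilibrium_thermo import BAR_TO_ATM, R_KCAL, R_LATM
from .exceptions import ConfigError
from .spectra_io import EmissionSpectrum, KineticTrace, SpectralSeries

DEFAULT_GRID_NM = np.arange(290.0, 401.0, 1.0)
DEFAULT_EXCITATION_NM = 280.0
DEFAULT_INTENSITY_SCALE = 1.0e5

# default band shapes, chosen to mimic a Tyr-dominated folded band near
# 303 nm and a red-shifted solvent-exposed Trp band near 350 nm
FOLDED_BAND = None      # set below, after BasisBand is defined
UNFOLDED_BAND = None


@dataclass(frozen=True)
class BasisBand:
    """One Gaussian emission band.

    ``space="wavenumber"`` (default): Gaussian in nu = 1e7/lambda with
    width_sd in cm^-1 — the physically standard shape for emission bands.
    ``space="nm"``: Gaussian directly on the wavelength grid (testing aid).
    """

    center_nm: float
    width_sd: float
    amplitude_au: float = 1.0
    space: str = "wavenumber"

    def __post_init__(self) -> None:
        if self.width_sd <= 0:
            raise ConfigError("band width must be positive")
        if self.amplitude_au < 0:
            raise ConfigError("band amplitude must be non-negative")
        if self.space not in ("wavenumber", "nm"):
            raise ConfigError(f"unknown band space {self.space!r}")

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        if self.space == "wavenumber":
            coord = 1.0e7 / wl
            center = 1.0e7 / self.center_nm
        else:
            coord = wl
            center = self.center_nm
        return self.amplitude_au * np.exp(-0.5 * ((coord - center) / self.width_sd) ** 2)


FOLDED_BAND = BasisBand(center_nm=303.0, width_sd=1500.0)    # cm^-1
UNFOLDED_BAND = BasisBand(center_nm=350.0, width_sd=1800.0)  # cm^-1


@dataclass(frozen=True)
class StateSpec:
    """A conformational state: basis bands plus a linear free energy.

    G(x) = g0 - g_slope * x (kcal/mol), relative to the reference state;
    the population of state i at axis value x is
    exp(-G_i(x)/RT) / sum_j exp(-G_j(x)/RT).
    """

    name: str
    bands: tuple[BasisBand, ...]
    g0_kcal_mol: float = 0.0
    g_slope: float = 0.0    # kcal/mol per axis unit (M or bar)

    def spectrum(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(wavelengths_nm, dtype=float))
        for band in self.bands:
            out += band.evaluate(wavelengths_nm)
        return out


@dataclass(frozen=True)
class ScatteringSpec:
    """Pressure-induced scattering artifact near the excitation line.

    Above ``onset_bar`` a half-Gaussian tail (center at the excitation
    wavelength, short-wavelength edge of the grid) is added with relative
    amplitude ``growth_per_kbar2 * ((p - onset)/1000)**2`` of the protein
    signal's integrated intensity: scattering rises abruptly and
    superlinearly as aggregates accumulate above the onset.
    """

    onset_bar: float = 2700.0
    growth_per_kbar2: float = 2.0
    width_nm: float = 8.0

    def profile(self, wavelengths_nm: np.ndarray, excitation_nm: float) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        prof = np.exp(-0.5 * ((wl - excitation_nm) / self.width_nm) ** 2)
        total = prof.sum()
        return prof / total if total > 0 else prof


@dataclass
class TitrationConfig:
    """Full description of one synthetic spectral titration."""

    axis_kind: str
    axis_values: np.ndarray
    states: tuple[StateSpec, ...]
    temperature_K: float = 298.0
    noise_cv: float = 0.0
    seed: int | None = None
    wavelengths_nm: np.ndarray = field(default_factory=lambda: DEFAULT_GRID_NM.copy())
    excitation_nm: float = DEFAULT_EXCITATION_NM
    intensity_scale: float = DEFAULT_INTENSITY_SCALE
    equalize_state_intensity: bool = True
    scattering: ScatteringSpec | None = None

    def __post_init__(self) -> None:
        if self.axis_kind not in ("denaturant_M", "pressure_bar"):
            raise ConfigError(f"unknown axis_kind {self.axis_kind!r}")
        if self.seed is None:
            raise ConfigError("seed is mandatory (simulations must be reproducible)")
        if len(self.states) < 2:
            raise ConfigError("need at least two states (folded and unfolded)")
        if self.scattering is not None and self.axis_kind != "pressure_bar":
            raise ConfigError("scattering artifact only applies to a pressure axis")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        self.axis_values = np.asarray(self.axis_values, dtype=float)


@dataclass
class KineticConfig:
    """Synthetic ThT trace: sequential-model parameters plus additive noise."""

    k1_per_min: float
    k2_per_min: float
    times_min: np.ndarray
    k3_per_min: float = 0.0
    m_au: float = 1.0
    a_au: float = 0.0
    noise_sd_au: float = 0.0
    temperature_K: float = 310.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k1_per_min <= 0 or self.k2_per_min <= 0:
            raise ConfigError("rate constants k1, k2 must be positive")
        if self.seed is None:
            raise ConfigError("seed is mandatory (simulations must be reproducible)")
        if self.noise_sd_au < 0:
            raise ConfigError("noise_sd_au must be >= 0")
        self.times_min = np.asarray(self.times_min, dtype=float)


# --------------------------------------------------------------------------
# population weights and state spectra
# --------------------------------------------------------------------------

def state_weights(config: TitrationConfig) -> np.ndarray:
    """Boltzmann population of every state at every axis value; rows sum to 1.

    Returns an array of shape (n_axis, n_states).
    """
    rt = R_KCAL * config.temperature_K
    g = np.array(
        [
            [s.g0_kcal_mol - s.g_slope * x for s in config.states]
            for x in config.axis_values
        ]
    )
    g -= g.min(axis=1, keepdims=True)   # stabilize the softmax
    w = np.exp(-g / rt)
    return w / w.sum(axis=1, keepdims=True)


def state_basis_spectra(config: TitrationConfig) -> np.ndarray:
    """Basis spectrum of every state on the grid, shape (n_states, n_channels).

    With ``equalize_state_intensity`` each state is normalized to the same
    integrated intensity (``intensity_scale``), so mixture CSM is affine in
    the populations.
    """
    basis = np.vstack([s.spectrum(config.wavelengths_nm) for s in config.states])
    if config.equalize_state_intensity:
        sums = basis.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ConfigError("a state has zero integrated intensity on the grid")
        basis = basis / sums * config.intensity_scale
    return basis


def pure_state_spectrum(config: TitrationConfig, index: int) -> EmissionSpectrum:
    """Noise-free basis spectrum of one state (e.g. for CSM/phasor anchors)."""
    basis = state_basis_spectra(config)
    return EmissionSpectrum(
        wavelengths_nm=config.wavelengths_nm.copy(),
        intensities_au=basis[index],
        excitation_nm=config.excitation_nm,
        label=config.states[index].name,
    )


def generating_alpha(config: TitrationConfig) -> np.ndarray:
    """Population of the last state (unfolded) at every axis value.

    For a two-state config this is the exact generating fraction unfolded
    alpha = Keq/(1+Keq).
    """
    return state_weights(config)[:, -1]


def simulate_titration(config: TitrationConfig) -> SpectralSeries:
    """Render a spectral series from state populations, artifact, and noise."""
    rng = np.random.default_rng(config.seed)
    weights = state_weights(config)
    basis = state_basis_spectra(config)
    spectra = []
    for idx, x in enumerate(config.axis_values):
        clean = weights[idx] @ basis
        if (
            config.scattering is not None
            and x >= config.scattering.onset_bar
        ):
            rel = config.scattering.growth_per_kbar2 * ((x - config.scattering.onset_bar) / 1000.0) ** 2
            spike = rel * clean.sum() * config.scattering.profile(
                config.wavelengths_nm, config.excitation_nm
            )
            clean = clean + spike
        if config.noise_cv > 0:
            noisy = clean * (1.0 + config.noise_cv * rng.standard_normal(clean.size))
            clean = np.clip(noisy, 0.0, None)
        spectra.append(
            EmissionSpectrum(
                wavelengths_nm=config.wavelengths_nm.copy(),
                intensities_au=clean,
                excitation_nm=config.excitation_nm,
                label=f"x={x:g}",
            )
        )
    return SpectralSeries(
        axis_kind=config.axis_kind,
        axis_values=config.axis_values.copy(),
        spectra=spectra,
        shared_grid=True,
    )


def simulate_tht_trace(config: KineticConfig) -> KineticTrace:
    """ThT trace from the sequential model plus additive Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    params = KineticParams(
        k1_per_min=config.k1_per_min,
        k2_per_min=config.k2_per_min,
        k3_per_min=config.k3_per_min,
        m_au=config.m_au,
        a_au=config.a_au,
    )
    f = model_F(params, config.times_min)
    if config.noise_sd_au > 0:
        f = f + config.noise_sd_au * rng.standard_normal(f.size)
    return KineticTrace(
        times_min=config.times_min.copy(),
        intensities_au=f,
        temperature_K=config.temperature_K,
    )


# --------------------------------------------------------------------------
# convenience constructors for the standard study designs
# --------------------------------------------------------------------------

def pressure_slope_kcal_per_bar(delta_V_abs_ml_mol: float, temperature_K: float = 298.0) -> float:
    """Free-energy slope (kcal/mol per bar) equivalent to a |Delta_V| in ml/mol."""
    dv_l = delta_V_abs_ml_mol / 1000.0
    # logit slope per atm = dv_l/(R_latm T); convert to kcal/mol per bar
    return dv_l * BAR_TO_ATM * R_KCAL / R_LATM


def two_state_chemical(
    delta_G0_kcal_mol: float = 4.6,
    m_value_kcal_mol_M: float = 4.466,
    axis_values=None,
    *,
    seed: int,
    noise_cv: float = 0.0,
    temperature_K: float = 298.0,
    folded_band: BasisBand = FOLDED_BAND,
    unfolded_band: BasisBand = UNFOLDED_BAND,
    **kwargs,
) -> TitrationConfig:
    """Two-state chemical-denaturant titration config.

    Defaults mirror a marginally stable two-state domain: Delta_G0 = 4.6
    kcal/mol and m = 4.466 kcal mol^-1 M^-1, i.e. a midpoint near 1.03 M.
    """
    if axis_values is None:
        axis_values = np.arange(0.0, 3.01, 0.1)
    states = (
        StateSpec(name="folded", bands=(folded_band,)),
        StateSpec(
            name="unfolded",
            bands=(unfolded_band,),
            g0_kcal_mol=delta_G0_kcal_mol,
            g_slope=m_value_kcal_mol_M,
        ),
    )
    return TitrationConfig(
        axis_kind="denaturant_M",
        axis_values=axis_values,
        states=states,
        temperature_K=temperature_K,
        noise_cv=noise_cv,
        seed=seed,
        **kwargs,
    )


def two_state_pressure(
    delta_V_abs_ml_mol: float = 64.4,
    p_half_bar: float = 2900.0,
    axis_values=None,
    *,
    seed: int,
    noise_cv: float = 0.0,
    temperature_K: float = 298.0,
    scattering: ScatteringSpec | None = None,
    folded_band: BasisBand = FOLDED_BAND,
    unfolded_band: BasisBand = UNFOLDED_BAND,
    **kwargs,
) -> TitrationConfig:
    """Two-state pressure titration config (defaults: |Delta_V| = 64.4 ml/mol,
    p_1/2 = 2.9 kbar, 600 bar steps from 0 to 3.6 kbar)."""
    if axis_values is None:
        axis_values = np.arange(0.0, 3601.0, 600.0)
    slope = pressure_slope_kcal_per_bar(delta_V_abs_ml_mol, temperature_K)
    states = (
        StateSpec(name="folded", bands=(folded_band,)),
        StateSpec(
            name="unfolded",
            bands=(unfolded_band,),
            g0_kcal_mol=slope * p_half_bar,
            g_slope=slope,
        ),
    )
    return TitrationConfig(
        axis_kind="pressure_bar",
        axis_values=axis_values,
        states=states,
        temperature_K=temperature_K,
        noise_cv=noise_cv,
        seed=seed,
        scattering=scattering,
        **kwargs,
    )


def three_state_chemical(
    delta_G0_kcal_mol: float = 4.6,
    m_value_kcal_mol_M: float = 4.466,
    intermediate_band: BasisBand | None = None,
    intermediate_g0: float = 2.0,
    intermediate_slope: float = 2.8,
    axis_values=None,
    *,
    seed: int,
    noise_cv: float = 0.0,
    temperature_K: float = 298.0,
    **kwargs,
) -> TitrationConfig:
    """Hidden-state scenario (synthetic only): a third state with its own band.

    The intermediate's basis spectrum has no experimental counterpart here;
    the default (a band between the folded and unfolded centers) exists so
    that deviation-from-linearity detection has a positive control.
    """
    if axis_values is None:
        axis_values = np.arange(0.0, 3.01, 0.1)
    if intermediate_band is None:
        intermediate_band = BasisBand(center_nm=325.0, width_sd=1500.0)
    states = (
        StateSpec(name="folded", bands=(FOLDED_BAND,)),
        StateSpec(
            name="intermediate",
            bands=(intermediate_band,),
            g0_kcal_mol=intermediate_g0,
            g_slope=intermediate_slope,
        ),
        StateSpec(
            name="unfolded",
            bands=(UNFOLDED_BAND,),
            g0_kcal_mol=delta_G0_kcal_mol,
            g_slope=m_value_kcal_mol_M,
        ),
    )
    return TitrationConfig(
        axis_kind="denaturant_M",
        axis_values=axis_values,
        states=states,
        temperature_K=temperature_K,
        noise_cv=noise_cv,
        seed=seed,
        **kwargs,
    )
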