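# phasorfold

Analysis of protein folding, stability and aggregation from fluorescence
spectroscopy: spectral phasor plots, two-state equilibrium thermodynamics
under chemical and pressure perturbation, and sequential-kinetics fitting of
thioflavin-T (ThT) aggregation traces. Built for experiments of the kind used
to probe marginally stable domains such as the p53 DNA-binding core: intrinsic
Trp/Tyr emission recorded along a guanidine-hydrochloride (GuHCl) or high
hydrostatic pressure (HHP) axis, and ThT time courses of amyloid-like
aggregation.

Because raw spectra from such studies are rarely deposited, the package ships
a first-class synthetic-data generator that emulates the experiments' spectral
structure (Tyr-dominated folded band near 303 nm, red-shifted unfolded Trp
band near 350 nm, Boltzmann state populations, pressure-induced scattering
artifact, measurement noise), so the whole pipeline is testable end to end.

## What it computes

**Spectral observables.** The center of spectral mass (CSM) of an emission
scan, ν = Σ ν_k F_k / Σ F_k (wavenumber by default; red shift lowers ν), and
the fraction unfolded α = (ν − ν_i)/(ν_f − ν_i) normalized between folded and
unfolded endpoints. Light-scattering signal is summarized as the trapezoidal
area under the spectrum in a wavelength window.

**Spectral phasors.** The first-harmonic Fourier coefficients of a spectrum,
G = Σ I_k cos(2πnk/K)/Σ I_k and S = Σ I_k sin(2πnk/K)/Σ I_k. The phasor of a
mixture of two species lies, exactly, on the segment between the pure-species
phasors, so a strictly two-state titration traces a straight line; deviation
from that line reveals hidden states (e.g. molten-globule conformers) without
fitting any folding model, and a sharp turn of the trajectory marks the onset
of scattering-dominated spectra, i.e. aggregation.

**Equilibrium thermodynamics.** For a two-state equilibrium F ⇌ U,
K_eq = α/(1 − α) and ΔG = −RT ln K_eq. Along a denaturant axis the linear
extrapolation model ΔG(x) = ΔG₀ − m·x makes the logit ln(α/(1−α)) linear in x:
ordinary least squares over the transition region yields ΔG₀ (stability at
0 M), the m-value, and the midpoint ΔG₀/m. Along a pressure axis
ln(α/(1−α)) = (ΔV/RT)·p + ln K_eq(0), giving the unfolding volume change ΔV
(ml/mol, reported signed and as a magnitude) and the half-pressure p_½. The
transition midpoint can also be read model-independently from the maximum of
dα/dx.

**Aggregation kinetics.** The sequential first-order scheme N → I → U with
rate constants k₁, k₂ has closed-form species profiles; the ThT observable is
F(t) = m·[U](t)/N₀ + k₃t + a. Nonlinear least squares (multi-start over a
log-spaced rate grid) fits all five parameters; since F is symmetric under
k₁ ↔ k₂ the rates are reported as an ordered apparent pair, and a lag-phase
metric (time to 5% of plateau) distinguishes primed from nucleation-limited
aggregation.

## Worked example

```python
import numpy as np
import phasorfold as pf

# a noisy two-state GuHCl titration with DeltaG0 = 4.6 kcal/mol, m = 4.466
cfg = pf.two_state_chemical(4.6, 4.466, seed=42, noise_cv=0.02)
series = pf.simulate_titration(cfg)

# fraction unfolded from the CSM, anchored on the pure-state spectra
vi = pf.center_of_spectral_mass(pf.pure_state_spectrum(cfg, 0))
vf = pf.center_of_spectral_mass(pf.pure_state_spectrum(cfg, -1))
curve = pf.unfolding_curve(series, v_i=vi, v_f=vf)
fit = pf.fit_chemical_denaturation(curve)
print(f"Delta_G0 = {fit.delta_G0_kcal_mol:.2f} kcal/mol, "
      f"m = {fit.m_value_kcal_mol_M:.2f}, midpoint = {fit.midpoint:.2f} M")

# model-independent diagnostics from the phasor trajectory
traj = pf.trajectory(series)
print(f"collinearity = {pf.collinearity_statistic(traj):.2e}, "
      f"inflection = {pf.detect_inflection(traj)}")

# a ThT aggregation trace and its sequential-model fit
kin = pf.KineticConfig(k1_per_min=0.25, k2_per_min=2.22,
                       times_min=np.linspace(0, 40, 200),
                       m_au=100.0, a_au=2.0, noise_sd_au=1.0, seed=42)
kfit = pf.fit_trace(pf.simulate_tht_trace(kin))
print(f"k1 = {kfit.params.k1_per_min:.3f} min^-1, "
      f"k2 = {kfit.params.k2_per_min:.3f} min^-1, R^2 = {kfit.r_squared:.4f}")
```

Output:

```
Delta_G0 = 4.57 kcal/mol, m = 4.44, midpoint = 1.03 M
collinearity = 3.54e-03, inflection = None
k1 = 2.099 min^-1, k2 = 0.256 min^-1, R^2 = 0.9985
```

The fitted stability and m-value recover the generating values within the 2%
measurement noise; the collinearity statistic is at noise level (no hidden
state) and no aggregation inflection is present. The kinetic fit returns the
apparent rate pair in canonical (descending) order — the observable cannot
assign which rate belongs to N → I versus I → U.

The same stages are available from the shell via the `phasorfold` command
(`simulate-titration`, `simulate-kinetics`, `observables`, `phasor`,
`unfold-fit`, `pressure-fit`, `kinetics-fit`, and `run` for a configured,
manifest-producing pipeline).

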