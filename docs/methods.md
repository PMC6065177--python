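# Methods

## Scope and data model

The package analyzes two kinds of measurement:

* **Spectral series** — fluorescence emission scans (wavelength grid in nm,
  intensities in arbitrary units) ordered along one perturbation axis, either
  chemical denaturant concentration (molar GuHCl) or hydrostatic pressure
  (bar). The on-disk format is long/tidy CSV (one row per wavelength per
  spectrum) with fixed units per axis kind; there is deliberately no unit
  autodetection, because silent unit errors are the dominant failure mode in
  this domain.
* **Kinetic traces** — ThT fluorescence versus time (minutes).

Intensities may be zero but not negative; no baseline subtraction is applied
by default. Non-uniform wavelength grids are accepted everywhere; the phasor
transform linearly resamples them to the finest spacing present.

## Center of spectral mass and fraction unfolded

CSM is the intensity-weighted mean spectral position. The default scale is
wavenumber, ν_k = 10⁷/λ_k (cm⁻¹), the convention in which red shifts lower
the value and in which folded/unfolded endpoint values are customarily
quoted; a nm-scale option exists. The two scales are *not* equivalent (the
weighted mean does not commute with 1/λ), which is why the scale is an
explicit flag rather than a conversion.

Fraction unfolded normalizes the CSM series between a folded anchor v_i and
an unfolded anchor v_f; anchors default to the first and last series points
but can be supplied explicitly — necessary when the last recorded condition
is not fully unfolded, or is contaminated by aggregation scattering. Values
outside [0, 1] are preserved and flagged with a warning rather than clipped:
a non-monotone CSM series (e.g. a transient blue shift from a partially
shielded Trp) is precisely the signature of intermediate states that the
phasor diagnostics are designed to expose, and clipping would hide it.

## Spectral phasor

The phasor of a spectrum is its first discrete-Fourier coefficient
normalized by total intensity, with channel k of K carrying phase 2πnk/K
(zero-based, the recorded interval mapping to exactly one period; harmonic
n = 1 by default). The printed forms of this transform in the spectroscopy
literature sometimes omit the channel index; the k/K convention used here is
pinned by an exhaustive small-grid Fourier-oracle test, so the convention is
unambiguous in code even where notation in the field is loose.

Two properties carry all the interpretive weight and are tested as algebraic
identities:

* **Mixture exactness.** The phasor of w·A + (1−w)·B is an intensity-weighted
  convex combination of the phasors of A and B, hence lies on the segment
  between them. A strictly two-state series is therefore exactly collinear.
* **Boundedness.** For non-negative spectra the phasor is a weighted mean of
  unit vectors, so |P| ≤ 1.

The **collinearity statistic** is the maximum perpendicular distance of the
trajectory points from the line through the folded/unfolded anchor phasors,
normalized by the anchor separation (0 ⇔ perfectly two-state). Significance
is assessed against a Monte-Carlo null: the distribution of the statistic
over seeded two-state simulations at the measurement's noise level.

The **inflection detector** walks the trajectory and reports the first
interior vertex where the turning angle between the incoming and outgoing
segments exceeds a threshold (default 90°, robust to noise wobble). Segments
shorter than 5% of the trajectory's bounding-box diagonal are skipped so that
jitter between nearly coincident points (a stalled trajectory end) cannot
mimic a turn. A sharp turn marks departure from the folding path toward
scattering-dominated spectra — the phasor signature of aggregation.

## Equilibrium thermodynamics

Two-state analysis throughout: K_eq = α/(1−α), ΔG = −RT ln K_eq with
R = 0.00198 kcal K⁻¹ mol⁻¹ and T = 298 K by default.

* **Chemical axis.** ΔG(x) = ΔG₀ − m·x, so the logit of α is linear in
  denaturant. OLS over the transition window (default α ∈ (0.1, 0.9), where
  the logit is well conditioned and baseline-dominated points are excluded;
  user-overridable) gives ΔG₀ = −RT·intercept, m = RT·slope, midpoint ΔG₀/m.
  Standard errors propagate from the regression. No sloping native/unfolded
  baselines are modeled; normalization is assumed handled by the endpoint
  anchors.
* **Pressure axis.** ln(α/(1−α)) = (ΔV/RT)p + ln K_eq(0). The unit pipeline
  is fixed: input bar → atm (×0.98692), slope·RT with R = 0.082
  L·atm·K⁻¹·mol⁻¹, ×1000 to ml/mol. |ΔV| is reported alongside a signed ΔV
  that is negative when unfolding advances with pressure — tables in the
  experimental literature customarily print the magnitude while text quotes
  the negative sign, so both are emitted. p_½ is the logit zero crossing,
  reported in bar.
* **Derivative midpoint.** As a model-independent cross-check, the midpoint
  is also computed as the arg-max of dα/dx of the fitted sigmoid on a dense
  grid (numerical gradient); for any two-state curve this coincides with the
  logit zero crossing to grid resolution. Multiple comparable derivative
  maxima trigger a warning listing all of them.

## Sequential aggregation kinetics

The scheme N → I → U (native → pre-amyloidogenic intermediate → end state)
with first-order rates k₁, k₂ has closed forms

    [N] = N₀ e^{−k₁t}
    [I] = N₀ k₁/(k₁−k₂) (e^{−k₂t} − e^{−k₁t})
    [U] = N₀/(k₁−k₂) (k₁ − k₂ + k₂e^{−k₁t} − k₁e^{−k₂t})

and the observable F(t) = m·[U]/N₀ + k₃t + a, where m is the amplitude
(monomer concentration × ThT yield of the end state), k₃ a small instrumental
drift and a the intercept. Numerical choices: the generic branch is written
with expm1 so F(0) = a holds exactly and the k₁ ↔ k₂ exchange symmetry is
exact in floating point; the removable singularity at k₁ = k₂ switches to the
analytic limit [U]/N₀ = 1 − (1+kt)e^{−kt} when |k₁−k₂| < 10⁻⁸·max(k₁,k₂),
continuous with the generic branch to < 10⁻⁶. The closed forms are validated
against adaptive numerical integration of the rate equations (dN/dt = −k₁N,
dI/dt = +k₁N − k₂I, dU/dt = k₂I) to < 10⁻⁸·N₀.

Fitting is nonlinear least squares (Levenberg–Marquardt) on
(log k₁, log k₂, m, a, k₃) — log-rates keep the constants positive. Without
an initial guess, a deterministic 5×5 log-spaced grid of rate pairs over
[10⁻³, 10] min⁻¹ is tried and the lowest residual wins (first-best in grid
order). Because F is exchange-symmetric in (k₁, k₂), the two rates are only
identifiable as an unordered *apparent* pair; fits are reported in canonical
order k₁ ≥ k₂ (switchable off), and the report notes that assignment to the
N→I versus I→U step is not possible from F alone. The drift k₃ can be fixed
at zero for protocols known to be drift-free. Standard errors come from the
Gauss–Newton covariance at the optimum; R² = 1 − SS_res/SS_tot.

The **lag-phase metric** t_lag is the time at which the drift-corrected
fitted signal reaches 5% of the plateau amplitude (root-bracketed on the
fitted [U] fraction); the lag flag compares t_lag to a user threshold
(default 5 min). The 5% operationalization is this package's choice — the
qualitative lag/no-lag language of the experimental literature does not
define one.

## Synthetic-data generator

The generator exists so that every downstream stage has exact ground truth.

* **Basis bands** are Gaussian in wavenumber space (the physically standard
  shape for emission bands), converted to the nm grid; an nm-space option is
  provided for testing. Defaults emulate a Tyr-dominated folded band at
  303 nm (σ = 1500 cm⁻¹) and a red-shifted unfolded Trp band at 350 nm
  (σ = 1800 cm⁻¹) on a 290–400 nm grid at 1 nm.
* **Populations** follow Boltzmann weights of per-state linear free energies
  G_i(x) = G₀,i − s_i·x, which for two states is exactly the equilibrium
  model the fits invert (convenience constructors accept (ΔG₀, m) or
  (|ΔV|, p_½) directly). Default two-state constants, ΔG₀ = 4.6 kcal/mol
  with m = 4.466 kcal mol⁻¹ M⁻¹ (midpoint 1.03 M) and |ΔV| = 64.4 ml/mol
  with p_½ = 2.9 kbar at 600-bar steps, sit in the regime of a marginally
  stable ~25 kDa domain.
* **Equal state intensities.** State basis spectra are normalized to equal
  integrated intensity by default, which makes the mixture CSM exactly affine
  in the population fraction, so the downstream-recomputed α equals the
  generating α to machine precision. Real proteins violate this badly — the
  folded-state emission of a Tyr-quenched domain can be several-fold brighter
  than the unfolded state — in which case CSM-derived α is a spectroscopic
  order parameter rather than a strict population fraction. Passing recovery
  tests therefore certify the *inversion machinery*, not the equal-brightness
  assumption; the flag can be turned off to study the resulting bias.
* **Scattering artifact.** Above an onset pressure (default 2.7 kbar) a
  half-Gaussian tail of a band centered at the excitation wavelength (280 nm,
  σ = 8 nm) is added with relative amplitude 2.0·((p − onset)/kbar)² of the
  protein signal. The quadratic growth reflects the abrupt, accelerating rise
  of scattering as aggregates accumulate; no published functional form exists
  for this artifact, so the law and coefficient are this package's model of
  "abrupt onset" (a dominant spike within ~1 kbar of onset).
* **Noise** is multiplicative Gaussian for spectra (coefficient of variation
  of intensity; default study conditions use 1–2%) and additive Gaussian for
  ThT traces. A seed is mandatory; output is bit-reproducible given the seed.

Not emulated: photophysics (quantum yields, Tyr→Trp FRET), sloping baselines,
instrument spectral response, aggregate size distributions. The hidden-state
(three-state) scenario uses a synthetic intermediate band at 325 nm with its
own linear free energy — there is no experimental reference spectrum for such
an intermediate, so hidden-state results are positive controls for the
detector, not simulations of a specific protein.

## Study conditions used by the recovery checks

Problem sizes were chosen as the smallest that make each check sharp:

* Chemical recovery: noiseless titrations on a 0–6 M grid at 0.05 M over
  ΔG₀ ∈ [1, 8] kcal/mol × m ∈ [2, 6] kcal mol⁻¹ M⁻¹ (recovery to < 10⁻⁶
  relative); noise robustness at 2% cv with 12 points spanning 0–2.2 M,
  500 replicates (bias ≪ 5%).
* Pressure recovery: |ΔV| ∈ [40, 120] ml/mol, p_½ = 2 kbar, 0–4 kbar at
  100 bar (recovery to < 0.1%).
* Kinetic recovery: noiseless 200-point traces recover all five parameters
  to ≪ 0.1%. The noisy condition (1% of amplitude, 200 points) samples
  densely over the fast rise (0–10 min at 0.1-min steps, then to 100 min)
  and fixes k₃ = 0, mirroring a protocol designed to resolve a fast phase;
  with uniform sampling and a free drift term the fast rate's Cramér–Rao
  bound alone exceeds 5% at this noise level, i.e. the information simply
  is not in such a trace.
* Hidden-state detection: the two-state noise null uses 1000 seeded
  replicates at 1% cv; the three-state statistic exceeds its 99th percentile
  by over an order of magnitude.
* Inflection detection: 200 seeded replicates at 1% cv with onset 2.7 kbar
  on a 0–3.6 kbar/600 bar grid; detection at the first post-onset point in
  100% of replicates, zero false positives without the artifact.

## Known limitations

* All equilibrium fitting is strictly two-state; three-state equilibrium
  models and global (SVD-style) spectral fitting are out of scope. The
  phasor diagnostics *detect* extra states but do not quantify them.
* The CSM→α→logit route assumes the endpoint anchors are trustworthy;
  anchor error enters ΔG₀ roughly linearly through the logit.
* The kinetic model is the minimal sequential scheme; nucleation–elongation
  mechanisms with secondary processes are not covered, and the drift term is
  a phenomenological catch-all.
* Rate pairs with large ratio are asymmetrically identifiable from F(t): the
  slow rate is pinned by the main rise while the fast rate lives only in the
  early curvature, so its variance is intrinsically larger at equal noise.
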