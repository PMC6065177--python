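"""Two-state equilibrium thermodynamics of protein unfolding.

For a two-state equilibrium F <-> U with fraction unfolded alpha, the
equilibrium constant is Keq = alpha/(1-alpha) and the free energy of
unfolding is Delta_G = -R*T*ln(Keq). Under the linear extrapolation model
Delta_G(x) = Delta_G0 - m*x along a chemical-denaturant axis, so the logit
ln(alpha/(1-alpha)) is linear in denaturant concentration; the intercept of
an ordinary least-squares fit gives Delta_G0 (the stability at zero
denaturant) and the slope gives the m-value. Along a pressure axis,

    ln(alpha/(1-alpha)) = (Delta_V / R T) * p + ln Keq(0),

so the slope yields the unfolding volume change Delta_V. Conventions:
Delta_G0 is reported positive for a stable protein; Delta_V of unfolding is
reported negative when pressure drives unfolding, with the magnitude
alongside (experimental tables customarily print |Delta_V|).

Units are fixed: R = 0.00198 kcal K^-1 mol^-1 for free energies, R = 0.082
L atm K^-1 mol^-1 for volumes; pressure input is bar, converted internally
to atm, and Delta_V is reported in ml/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateFitWarning,
    DomainError,
    FlatCurveError,
    InsufficientDataError,
    NonUnimodalDerivativeWarning,
)
from .spectral_observables import UnfoldingCurve

R_KCAL = 0.00198     # kcal K^-1 mol^-1
R_LATM = 0.082       # L atm K^-1 mol^-1
BAR_TO_ATM = 0.98692
DEFAULT_TEMPERATURE_K = 298.0
DEFAULT_ALPHA_WINDOW = (0.1, 0.9)


@dataclass
class ThermoFit:
    """Result of a two-state logit regression along one perturbation axis.

    ``slope_logit`` and ``intercept_logit`` are the raw regression
    coefficients (logit per axis unit: per M for chemical, per atm for
    pressure). Derived quantities:

    * chemical: delta_G0 = -R*T*intercept (kcal/mol), m_value = R*T*slope
      (kcal mol^-1 M^-1), midpoint = delta_G0/m_value (M);
    * pressure: |Delta_V| = slope*R*T*1000 (ml/mol), signed Delta_V negative
      when unfolding advances with pressure, midpoint = p_1/2 (bar).
    """

    kind: str                       # "chemical" | "pressure"
    delta_G0_kcal_mol: float
    slope_logit: float
    intercept_logit: float
    midpoint: float
    temperature_K: float
    window: tuple[float, float]
    n_points_used: int
    r_squared: float
    converged: bool
    m_value_kcal_mol_M: float | None = None
    delta_V_ml_mol: float | None = None        # signed
    delta_V_abs_ml_mol: float | None = None
    stderr: dict = field(default_factory=dict)
    midpoint_extrapolated: bool = False

    def predict_alpha(self, axis_values) -> np.ndarray:
        """Fitted two-state sigmoid alpha(x) on arbitrary axis values (native units)."""
        x = np.asarray(axis_values, dtype=float)
        if self.kind == "pressure":
            x = x * BAR_TO_ATM
        logit = self.intercept_logit + self.slope_logit * x
        return 1.0 / (1.0 + np.exp(-logit))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "delta_G0_kcal_mol": self.delta_G0_kcal_mol,
            "slope_logit": self.slope_logit,
            "intercept_logit": self.intercept_logit,
            "midpoint": self.midpoint,
            "midpoint_units": "M" if self.kind == "chemical" else "bar",
            "temperature_K": self.temperature_K,
            "window": list(self.window),
            "n_points_used": self.n_points_used,
            "r_squared": self.r_squared,
            "converged": self.converged,
            "m_value_kcal_mol_M": self.m_value_kcal_mol_M,
            "delta_V_ml_mol": self.delta_V_ml_mol,
            "delta_V_abs_ml_mol": self.delta_V_abs_ml_mol,
            "stderr": dict(self.stderr),
            "midpoint_extrapolated": self.midpoint_extrapolated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThermoFit":
        return cls(
            kind=d["kind"],
            delta_G0_kcal_mol=d["delta_G0_kcal_mol"],
            slope_logit=d["slope_logit"],
            intercept_logit=d["intercept_logit"],
            midpoint=d["midpoint"],
            temperature_K=d["temperature_K"],
            window=tuple(d["window"]),
            n_points_used=d["n_points_used"],
            r_squared=d["r_squared"],
            converged=d["converged"],
            m_value_kcal_mol_M=d.get("m_value_kcal_mol_M"),
            delta_V_ml_mol=d.get("delta_V_ml_mol"),
            delta_V_abs_ml_mol=d.get("delta_V_abs_ml_mol"),
            stderr=dict(d.get("stderr", {})),
            midpoint_extrapolated=d.get("midpoint_extrapolated", False),
        )


def keq_from_alpha(alpha):
    """Equilibrium constant Keq = alpha/(1-alpha) for alpha strictly in (0, 1)."""
    a = np.asarray(alpha, dtype=float)
    if np.any((a <= 0.0) | (a >= 1.0)):
        raise DomainError("alpha must lie strictly in (0, 1)")
    out = a / (1.0 - a)
    return float(out) if np.isscalar(alpha) or out.ndim == 0 else out


def _transition_logits(curve: UnfoldingCurve, window: tuple[float, float]):
    lo, hi = window
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"alpha window must satisfy 0 < lo < hi < 1, got {window}")
    alpha = curve.alpha
    mask = (alpha > lo) & (alpha < hi) & np.isfinite(alpha)
    n_dropped = int(alpha.size - mask.sum())
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} transition point(s) with alpha in {window}; need >= 3"
        )
    x = curve.axis_values[mask]
    logit = np.log(alpha[mask] / (1.0 - alpha[mask]))
    bad = ~np.isfinite(logit)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} non-finite logit value(s)", stacklevel=3)
        x, logit = x[~bad], logit[~bad]
        if x.size < 3:
            raise InsufficientDataError("fewer than 3 finite logit values in window")
    return x, logit, n_dropped


def fit_chemical_denaturation(
    curve: UnfoldingCurve,
    window: tuple[float, float] = DEFAULT_ALPHA_WINDOW,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> ThermoFit:
    """Linear-extrapolation fit of a chemical (denaturant) unfolding curve.

    OLS of ln(alpha/(1-alpha)) against denaturant concentration over the
    transition window (default alpha in (0.1, 0.9), where the logit is well
    conditioned). Returns Delta_G0 (kcal/mol), the m-value
    (kcal mol^-1 M^-1) and the transition midpoint Delta_G0/m (M).
    """
    x, logit, _ = _transition_logits(curve, window)
    res = stats.linregress(x, logit)
    RT = R_KCAL * temperature_K
    delta_G0 = -RT * res.intercept
    m_value = RT * res.slope
    midpoint = float(delta_G0 / m_value) if m_value != 0 else float("nan")
    if res.slope == 0.0:
        warnings.warn("zero logit slope: degenerate chemical fit", DegenerateFitWarning)
    extrapolated = not (curve.axis_values.min() <= midpoint <= curve.axis_values.max())
    return ThermoFit(
        kind="chemical",
        delta_G0_kcal_mol=float(delta_G0),
        slope_logit=float(res.slope),
        intercept_logit=float(res.intercept),
        midpoint=midpoint,
        temperature_K=temperature_K,
        window=tuple(window),
        n_points_used=int(x.size),
        r_squared=float(res.rvalue**2),
        converged=bool(res.slope != 0.0 and np.isfinite(res.slope)),
        m_value_kcal_mol_M=float(m_value),
        stderr={
            "delta_G0_kcal_mol": float(RT * res.intercept_stderr),
            "m_value_kcal_mol_M": float(RT * res.stderr),
        },
        midpoint_extrapolated=bool(extrapolated),
    )


def fit_pressure_denaturation(
    curve: UnfoldingCurve,
    window: tuple[float, float] = DEFAULT_ALPHA_WINDOW,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> ThermoFit:
    """Volume-change fit of a pressure unfolding curve.

    OLS of ln(alpha/(1-alpha)) against pressure (bar converted to atm).
    |Delta_V| = slope * R * T scaled to ml/mol; the signed Delta_V of
    unfolding is negative when unfolding advances with pressure (positive
    logit slope). The midpoint p_1/2 (bar) is the logit zero crossing.
    """
    x_bar, logit_dummy, _ = _transition_logits(curve, window)
    x_atm = x_bar * BAR_TO_ATM
    res = stats.linregress(x_atm, logit_dummy)
    RT_latm = R_LATM * temperature_K
    dv_abs = abs(res.slope) * RT_latm * 1000.0      # ml/mol
    dv_signed = -np.sign(res.slope) * dv_abs if res.slope != 0 else 0.0
    degenerate = res.slope == 0.0
    if degenerate:
        warnings.warn("zero logit slope: degenerate pressure fit; Delta_V = 0",
                      DegenerateFitWarning)
        midpoint_bar = float("nan")
    else:
        midpoint_bar = float((-res.intercept / res.slope) / BAR_TO_ATM)
    delta_G0 = -R_KCAL * temperature_K * res.intercept
    extrapolated = degenerate or not (
        curve.axis_values.min() <= midpoint_bar <= curve.axis_values.max()
    )
    return ThermoFit(
        kind="pressure",
        delta_G0_kcal_mol=float(delta_G0),
        slope_logit=float(res.slope),
        intercept_logit=float(res.intercept),
        midpoint=midpoint_bar,
        temperature_K=temperature_K,
        window=tuple(window),
        n_points_used=int(x_bar.size),
        r_squared=float(res.rvalue**2),
        converged=bool(not degenerate and np.isfinite(res.slope)),
        delta_V_ml_mol=float(dv_signed),
        delta_V_abs_ml_mol=float(dv_abs),
        stderr={"delta_V_abs_ml_mol": float(res.stderr * RT_latm * 1000.0)},
        midpoint_extrapolated=bool(extrapolated),
    )


def midpoint_from_derivative(axis_values, alpha_values) -> float:
    """Axis value maximizing d(alpha)/dx of a fitted transition curve.

    Intended for a smooth fitted sigmoid evaluated on a dense grid (the
    first-derivative readout of the transition midpoint). Warns if the
    derivative has multiple interior local maxima; raises FlatCurveError
    when the curve is flat.
    """
    x = np.asarray(axis_values, dtype=float)
    a = np.asarray(alpha_values, dtype=float)
    if x.size < 5:
        raise InsufficientDataError("need >= 5 grid points to differentiate")
    deriv = np.gradient(a, x)
    span = float(np.ptp(a))
    if span <= 0.0 or np.max(np.abs(deriv)) <= 1e-12 * max(1.0, span):
        raise FlatCurveError("curve has no derivative maximum (flat)")
    interior = np.arange(1, x.size - 1)
    is_max = (deriv[interior] >= deriv[interior - 1]) & (deriv[interior] >= deriv[interior + 1])
    peaks = interior[is_max]
    significant = peaks[deriv[peaks] > 0.5 * deriv.max()]
    if significant.size > 1:
        warnings.warn(
            f"derivative has {significant.size} comparable local maxima at "
            f"x = {x[significant].round(4).tolist()}",
            NonUnimodalDerivativeWarning,
        )
    return float(x[int(np.argmax(deriv))])
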