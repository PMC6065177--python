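"""Sequential first-order aggregation kinetics N -> I -> U and ThT trace fitting.

The model is two consecutive irreversible first-order steps with rate
constants k1 and k2 (min^-1), starting from pure native protein N0:

    [N](t) = N0 exp(-k1 t)
    [I](t) = N0 k1/(k1-k2) (exp(-k2 t) - exp(-k1 t))
    [U](t) = N0/(k1-k2) (k1 - k2 + k2 exp(-k1 t) - k1 exp(-k2 t))

The thioflavin-T observable is proportional to the end product plus an
instrumental drift and offset:

    F(t) = m * [U](t)/N0 + k3 t + a

F is symmetric under k1 <-> k2, so the two rate constants are only
identifiable as an unordered pair ("apparent" constants); fits are reported
in the canonical order k1 >= k2 unless disabled. The removable singularity
at k1 = k2 is evaluated through its analytic limit
[U]/N0 -> 1 - (1 + k t) exp(-k t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import (
    ConfigError,
    DomainError,
    FitFailureError,
    InsufficientDataError,
    UndefinedLagError,
    ValidationError,
)
from .spectra_io import KineticTrace

_EQUAL_RATE_RTOL = 1e-8


@dataclass
class KineticParams:
    """Parameters of the sequential model and the ThT observable."""

    k1_per_min: float
    k2_per_min: float
    k3_per_min: float = 0.0     # drift (a.u. min^-1)
    m_au: float = 1.0           # amplitude: monomer concentration x ThT yield
    a_au: float = 0.0           # intercept at t = 0
    N0: float = 1.0

    def __post_init__(self) -> None:
        if self.k1_per_min <= 0 or self.k2_per_min <= 0:
            raise ConfigError("rate constants k1, k2 must be positive")
        if self.m_au < 0:
            raise ConfigError("amplitude m must be non-negative")

    def canonical(self) -> "KineticParams":
        """Same parameters with k1 >= k2 (the observable is k1<->k2 symmetric)."""
        if self.k1_per_min >= self.k2_per_min:
            return self
        return KineticParams(
            k1_per_min=self.k2_per_min,
            k2_per_min=self.k1_per_min,
            k3_per_min=self.k3_per_min,
            m_au=self.m_au,
            a_au=self.a_au,
            N0=self.N0,
        )


@dataclass
class KineticFit:
    """Converged nonlinear least-squares fit of a ThT trace."""

    params: KineticParams
    stderr: dict
    r_squared: float
    converged: bool
    canonical_ordered: bool = True
    n_points: int = 0
    residual_ss: float = float("nan")
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "kind": "kinetic",
            "k1_per_min": self.params.k1_per_min,
            "k2_per_min": self.params.k2_per_min,
            "k3_per_min": self.params.k3_per_min,
            "m_au": self.params.m_au,
            "a_au": self.params.a_au,
            "N0": self.params.N0,
            "stderr": dict(self.stderr),
            "r_squared": self.r_squared,
            "converged": self.converged,
            "canonical_ordered": self.canonical_ordered,
            "n_points": self.n_points,
            "residual_ss": self.residual_ss,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticFit":
        return cls(
            params=KineticParams(
                k1_per_min=d["k1_per_min"],
                k2_per_min=d["k2_per_min"],
                k3_per_min=d["k3_per_min"],
                m_au=d["m_au"],
                a_au=d["a_au"],
                N0=d.get("N0", 1.0),
            ),
            stderr=dict(d.get("stderr", {})),
            r_squared=d["r_squared"],
            converged=d["converged"],
            canonical_ordered=d.get("canonical_ordered", True),
            n_points=d.get("n_points", 0),
            residual_ss=d.get("residual_ss", float("nan")),
            note=d.get("note", ""),
        )


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be non-negative")
    return t


def _u_fraction(k1: float, k2: float, t: np.ndarray) -> np.ndarray:
    """[U](t)/N0, with the k1 == k2 removable singularity handled analytically.

    The generic branch is written with expm1 so that U(0) = 0 holds exactly
    and the k1 <-> k2 exchange symmetry is exact in floating point:
    (k1 - k2 + k2 e^{-k1 t} - k1 e^{-k2 t})/(k1 - k2)
      = (k2 expm1(-k1 t) - k1 expm1(-k2 t))/(k1 - k2).
    """
    if abs(k1 - k2) < _EQUAL_RATE_RTOL * max(k1, k2):
        k = 0.5 * (k1 + k2)
        return -np.expm1(-k * t) - k * t * np.exp(-k * t)
    return (k2 * np.expm1(-k1 * t) - k1 * np.expm1(-k2 * t)) / (k1 - k2)


def species_profiles(params: KineticParams, times) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form ([N], [I], [U]) concentration profiles at the given times.

    Mass is conserved: [N] + [I] + [U] = N0 at every time.
    """
    t = _check_times(times)
    k1, k2, n0 = params.k1_per_min, params.k2_per_min, params.N0
    n = n0 * np.exp(-k1 * t)
    if abs(k1 - k2) < _EQUAL_RATE_RTOL * max(k1, k2):
        k = 0.5 * (k1 + k2)
        i = n0 * k * t * np.exp(-k * t)
    else:
        i = n0 * k1 / (k1 - k2) * (np.exp(-k2 * t) - np.exp(-k1 * t))
    u = n0 * _u_fraction(k1, k2, t)
    return n, i, u


def intermediate_peak_time(params: KineticParams) -> float:
    """Time at which the intermediate [I] is maximal: ln(k1/k2)/(k1-k2)."""
    k1, k2 = params.k1_per_min, params.k2_per_min
    if abs(k1 - k2) < _EQUAL_RATE_RTOL * max(k1, k2):
        return 1.0 / (0.5 * (k1 + k2))
    return float(np.log(k1 / k2) / (k1 - k2))


def model_F(params: KineticParams, times) -> np.ndarray:
    """ThT observable F(t) = m * [U](t)/N0 + k3 t + a."""
    t = _check_times(times)
    return (
        params.m_au * _u_fraction(params.k1_per_min, params.k2_per_min, t)
        + params.k3_per_min * t
        + params.a_au
    )


def _residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray, fix_k3: bool) -> np.ndarray:
    # theta = (log k1, log k2, m, a[, k3]); rates in log space keep them positive.
    # Clamp the log-rates so a wild LM step cannot overflow exp().
    k1, k2 = np.exp(np.clip(theta[0], -30.0, 30.0)), np.exp(np.clip(theta[1], -30.0, 30.0))
    m, a = theta[2], theta[3]
    k3 = 0.0 if fix_k3 else theta[4]
    return m * _u_fraction(k1, k2, t) + k3 * t + a - y


_MULTISTART_RATES = np.logspace(-3, 1, 5)   # min^-1


def fit_trace(
    trace: KineticTrace,
    init: KineticParams | None = None,
    fix_k3: bool = False,
    canonical_order: bool = True,
) -> KineticFit:
    """Nonlinear least-squares fit of the sequential model to a ThT trace.

    Without an initial guess, a deterministic 5x5 log-spaced grid of
    (k1, k2) starting pairs over [1e-3, 10] min^-1 is tried and the lowest
    residual wins (the first best in grid order; the k1<->k2 swapped
    optimum is equivalent by symmetry). Standard errors come from the
    Gauss-Newton covariance at the optimum; R^2 is 1 - SS_res/SS_tot.
    """
    t = trace.times_min
    y = trace.intensities_au
    if t.size < 5:
        raise InsufficientDataError("kinetic fitting needs at least 5 points")
    if np.ptp(y) == 0.0:
        raise ValidationError("trace intensities are constant; nothing to fit")

    span = float(np.ptp(y))
    starts: list[np.ndarray] = []
    if init is not None:
        base = [np.log(init.k1_per_min), np.log(init.k2_per_min), init.m_au, init.a_au]
        if not fix_k3:
            base.append(init.k3_per_min)
        starts.append(np.array(base))
    else:
        for ka in _MULTISTART_RATES:
            for kb in _MULTISTART_RATES:
                base = [np.log(ka), np.log(kb), span, float(y[0])]
                if not fix_k3:
                    base.append(0.0)
                starts.append(np.array(base))

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                _residuals, x0, args=(t, y, fix_k3), method="lm", max_nfev=2000
            )
        except Exception:
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost - 1e-15 * max(1.0, best.cost):
            best = sol
    if best is None:
        raise FitFailureError(
            f"sequential-model fit failed from all {len(starts)} start(s)"
        )

    k1, k2 = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    m, a = float(best.x[2]), float(best.x[3])
    k3 = 0.0 if fix_k3 else float(best.x[4])
    note = ""
    if abs(m) < 1e-9 * max(1.0, span):
        note = "flat amplitude (m ~ 0); rate constants not identifiable"
    # fitted m can come out negative from a pathological start; fold the sign
    # into the observable is impossible (U >= 0), so clamp via abs for params
    params = KineticParams(
        k1_per_min=k1, k2_per_min=k2, k3_per_min=k3, m_au=abs(m), a_au=a
    )
    swapped = False
    if canonical_order and params.k1_per_min < params.k2_per_min:
        params = params.canonical()
        swapped = True

    ss_res = float(2.0 * best.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    # covariance of (log k1, log k2, m, a[, k3]) via J^T J pseudo-inverse
    stderr: dict[str, float] = {}
    dof = t.size - best.x.size
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.pinv(jtj) * ss_res / dof
            sd = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            sd_k1 = k1 * sd[0]    # delta-method from log-rate to rate
            sd_k2 = k2 * sd[1]
            if swapped:
                sd_k1, sd_k2 = sd_k2, sd_k1
            stderr = {
                "k1_per_min": float(sd_k1),
                "k2_per_min": float(sd_k2),
                "m_au": float(sd[2]),
                "a_au": float(sd[3]),
            }
            if not fix_k3:
                stderr["k3_per_min"] = float(sd[4])
        except np.linalg.LinAlgError:
            pass

    return KineticFit(
        params=params,
        stderr=stderr,
        r_squared=float(r2),
        converged=True,
        canonical_ordered=canonical_order,
        n_points=int(t.size),
        residual_ss=ss_res,
        note=note or ("apparent rate constants; k1/k2 assignment to N->I vs I->U "
                      "is not identifiable from F(t)"),
    )


def lag_phase_flag(
    fit: KineticFit,
    threshold_min: float = 5.0,
    fraction: float = 0.05,
) -> tuple[bool, float]:
    """Lag-time metric of a fitted trace and a boolean lag-phase call.

    t_lag is the time at which the drift-corrected fitted signal reaches
    ``fraction`` (default 5%) of the plateau amplitude m, found by root
    bracketing on the fitted [U] fraction. The flag is True when t_lag
    exceeds ``threshold_min`` minutes. Undefined for m ~ 0.
    """
    if not fit.converged:
        raise UndefinedLagError("lag phase undefined for a non-converged fit")
    p = fit.params
    if p.m_au <= 0 or "m ~ 0" in fit.note:
        raise UndefinedLagError("lag phase undefined for zero-amplitude fit")
    k1, k2 = p.k1_per_min, p.k2_per_min
    f = lambda t: _u_fraction(k1, k2, np.asarray(t)) - fraction
    t_hi = 1.0
    while f(t_hi) < 0:
        t_hi *= 2.0
        if t_hi > 1e9:
            raise UndefinedLagError("fitted signal never reaches the lag fraction")
    t_lag = float(optimize.brentq(f, 0.0, t_hi, xtol=1e-10))
    return t_lag > threshold_min, t_lag
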