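"""Polynomial pressure dependence of chemical shifts.

The pressure response of a resonance in the 0.1–200 MPa range is modelled
as a low-degree Taylor polynomial in ΔP = P − P₀,

    δ(P) = δ₀ + B₁ ΔP + B₂ ΔP² (+ B₃ ΔP³),

with ΔP expressed internally in GPa so that the design matrix is well
conditioned and the coefficients carry the customary units ppm·GPa⁻¹ and
ppm·GPa⁻².  Degree 2 suffices for random-coil peptides; degree 3 is
supported for small molecules with a stronger curvature.

Fits are ordinary (optionally weighted) least squares with 95% confidence
intervals from the t-distribution with n − (degree+1) degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError, RatioUndefinedError, UsageError

__all__ = [
    "PressurePoint",
    "PressureSeries",
    "PolynomialFit",
    "ExtremumResult",
    "RatioResult",
    "evaluate_shift",
    "fit_series",
    "extremum_pressure",
    "curvature_ratio",
    "P0_DEFAULT",
]

P0_DEFAULT = 0.1  # MPa, atmospheric reference pressure
_PACKAGED_RANGE = (0.1, 250.0)  # MPa; ceramic-cell limit


@dataclass(frozen=True)
class PressurePoint:
    pressure: float  # MPa
    shift: float     # ppm
    sigma: float | None = None  # optional per-point uncertainty, ppm


@dataclass
class PressureSeries:
    """Ordered (pressure, shift) observations for one resonance."""

    atom_id: tuple          # (residue, atom, variant-string)
    points: list            # list[PressurePoint], sorted by pressure
    temperature: float = 283.0  # K

    def __post_init__(self):
        pts = sorted(self.points, key=lambda p: p.pressure)
        self.points = pts
        for p in pts:
            if not _PACKAGED_RANGE[0] <= p.pressure <= _PACKAGED_RANGE[1]:
                warnings.warn(
                    f"pressure {p.pressure} MPa outside the calibrated "
                    f"range {_PACKAGED_RANGE} MPa", stacklevel=2)
                break

    @property
    def pressures(self) -> np.ndarray:
        return np.array([p.pressure for p in self.points], dtype=float)

    @property
    def shifts(self) -> np.ndarray:
        return np.array([p.shift for p in self.points], dtype=float)

    @property
    def sigmas(self) -> np.ndarray | None:
        sig = [p.sigma for p in self.points]
        if any(s is None for s in sig):
            return None
        return np.array(sig, dtype=float)

    def __len__(self):
        return len(self.points)

    @classmethod
    def from_arrays(cls, pressures, shifts, atom_id=("?", "?", "-"),
                    sigmas=None, temperature=283.0):
        sig = sigmas if sigmas is not None else [None] * len(pressures)
        pts = [PressurePoint(float(p), float(s), q)
               for p, s, q in zip(pressures, shifts, sig)]
        return cls(atom_id=tuple(atom_id), points=pts, temperature=temperature)


@dataclass(frozen=True)
class PolynomialFit:
    """Fitted Taylor coefficients with covariance and 95% intervals."""

    delta0: float            # ppm
    b1: float                # ppm / GPa
    b2: float                # ppm / GPa^2
    b3: float = 0.0          # ppm / GPa^3 (degree-3 fits only)
    degree: int = 2
    p0: float = P0_DEFAULT   # MPa
    covariance: np.ndarray | None = None   # (deg+1)x(deg+1), ppm-based units
    ci95: np.ndarray | None = None         # per-coefficient half-widths
    residual_sd: float = 0.0  # ppm
    n: int = 0

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.delta0, self.b1, self.b2, self.b3][: self.degree + 1])


def _dp_gpa(pressure_mpa, p0):
    return (np.asarray(pressure_mpa, dtype=float) - p0) / 1000.0


def evaluate_shift(fit: PolynomialFit, pressure):
    """Evaluate δ(P) (ppm) at one or many pressures given in MPa."""
    dp = _dp_gpa(pressure, fit.p0)
    out = fit.delta0 + fit.b1 * dp + fit.b2 * dp**2 + fit.b3 * dp**3
    return float(out) if np.isscalar(pressure) else out


def fit_series(series: PressureSeries, degree: int = 2, *,
               p0: float = P0_DEFAULT, weighted: bool = False) -> PolynomialFit:
    """Least-squares fit of the pressure polynomial to one series.

    Unweighted by default (the reference measurements carry no per-point
    uncertainties); with ``weighted=True`` the per-point ``sigma`` column is
    used for 1/σ² weighting.  Exact on noiseless polynomial data.
    """
    if degree not in (1, 2, 3):
        raise UsageError(f"degree must be 1, 2 or 3, got {degree}")
    press = series.pressures
    y = series.shifts
    n_distinct = len(np.unique(press))
    if n_distinct < degree + 1:
        raise FitError(
            f"need >= {degree + 1} distinct pressures for degree {degree}, "
            f"got {n_distinct}")
    dp = _dp_gpa(press, p0)
    X = np.vander(dp, degree + 1, increasing=True)
    if weighted:
        sig = series.sigmas
        if sig is None:
            raise UsageError("weighted fit requested but sigma values missing")
        if np.any(sig <= 0):
            raise FitError("non-positive sigma")
        w = 1.0 / sig
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y

    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < degree + 1:
        raise FitError("rank-deficient design matrix")
    resid = y - X @ beta
    n, p = len(y), degree + 1
    dof = n - p
    if dof > 0:
        if weighted:
            s2 = float(((resid / series.sigmas) ** 2).sum()) / dof
        else:
            s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(Xw.T @ Xw)
        tcrit = stats.t.ppf(0.975, dof)
        ci95 = tcrit * np.sqrt(np.diag(cov))
        residual_sd = math.sqrt(s2)
    else:
        cov = np.full((p, p), np.nan)
        ci95 = np.full(p, np.nan)
        residual_sd = 0.0

    coef = list(beta) + [0.0] * (3 - degree)
    return PolynomialFit(delta0=float(coef[0]), b1=float(coef[1]),
                         b2=float(coef[2]), b3=float(coef[3]), degree=degree,
                         p0=p0, covariance=cov, ci95=ci95,
                         residual_sd=residual_sd, n=n)


@dataclass(frozen=True)
class ExtremumResult:
    """Pressure of zero slope implied by a degree-2 fit."""

    dp_mpa: float          # P_ex - P0
    pressure_mpa: float    # P_ex
    in_range: bool         # inside the experimentally probed 0.1-200 MPa


def extremum_pressure(fit: PolynomialFit, upper_mpa: float = 200.0):
    """Extremum pressure P_ex = P₀ − B₁/(2 B₂), or None for a linear model.

    The result is flagged ``in_range=False`` when it falls outside the
    experimentally covered window (no extremum was observed below 200 MPa
    for any of the reference peptides).
    """
    if fit.degree < 2:
        raise UsageError("extremum requires a degree >= 2 fit")
    if fit.b2 == 0:
        return None
    dp_gpa = -fit.b1 / (2.0 * fit.b2)
    dp_mpa = dp_gpa * 1000.0
    pex = fit.p0 + dp_mpa
    return ExtremumResult(dp_mpa=dp_mpa, pressure_mpa=pex,
                          in_range=P0_DEFAULT <= pex <= upper_mpa)


@dataclass(frozen=True)
class RatioResult:
    ratio: float            # B2/B1, GPa^-1
    err: float | None       # quadrature-propagated 95% half-width
    unreliable: bool        # err >= |ratio| (bracketed in the tables)


def curvature_ratio(fit_or_record) -> RatioResult:
    """B₂/B₁ with its error propagated in quadrature.

    err = |B₂/B₁| · sqrt((σ_B1/B₁)² + (σ_B2/B₂)²), ignoring the B₁–B₂
    covariance; this reproduces the ± values printed alongside the
    reference tables.  The result is marked unreliable when the error is
    at least as large as the ratio itself.
    """
    b1, b2, e1, e2 = _coef_and_errors(fit_or_record)
    if b1 == 0:
        raise RatioUndefinedError("B2/B1 undefined for B1 = 0")
    ratio = b2 / b1
    if b2 == 0:
        return RatioResult(ratio=0.0, err=None, unreliable=True)
    if e1 is None or e2 is None:
        return RatioResult(ratio=ratio, err=None, unreliable=False)
    err = abs(ratio) * math.sqrt((e1 / b1) ** 2 + (e2 / b2) ** 2)
    return RatioResult(ratio=ratio, err=err, unreliable=err >= abs(ratio))


def _coef_and_errors(obj):
    if isinstance(obj, PolynomialFit):
        ci = obj.ci95
        return obj.b1, obj.b2, (None if ci is None else float(ci[1])), \
            (None if ci is None else float(ci[2]))
    # duck-typed CoefficientRecord
    return obj.b1, obj.b2, obj.err_b1, obj.err_b2
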