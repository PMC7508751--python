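"""Multi-state fast-exchange analysis of pressure-dependent shifts.

A nucleus exchanging rapidly between M conformational states shows one
population-averaged resonance

    ⟨δ⟩(ΔP) = Σ_j p_j(ΔP) δ_j(ΔP),     p_j ∝ exp(−ΔG_1j(ΔP) / RT),

with a pressure-dependent free-energy difference per transition

    ΔG(ΔP) = ΔG⁰ + ΔV⁰ ΔP + ½ (∂ΔV⁰/∂P) ΔP².

Units follow the convenient identity 1 mL·MPa = 1 J: ΔG⁰ in kJ·mol⁻¹,
ΔV⁰ in mL·mol⁻¹, ΔP in MPa, and ∂ΔV⁰/∂P (= −Δβ′, the compressibility
factor difference) in mL·mol⁻¹·GPa⁻¹.

Each state's intrinsic shift may itself depend on pressure through the
compression of the conformer; assuming this compression response is the
same in all states ("shared compression") the ensemble shift separates
exactly into a population-weighted δ₀ term plus one common polynomial
B₁ΔP + B₂ΔP², which is what :func:`fit_two_state` fits after the B
coefficients have been fixed at their random-coil values (or removed from
the data beforehand with :func:`compression_correct`).

For a two-state system the ensemble shift can be written via
tanh(ΔG/2RT); in the small-|ΔG/2RT| regime the fitted polynomial obeys
B₂/B₁ ≈ −½ Δβ′/ΔV, which links the curvature ratio of the reference
tables to an apparent local compressibility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .errors import FitError, NonIdentifiableError, RatioUndefinedError, UsageError
from .pressure import P0_DEFAULT, PolynomialFit, PressurePoint, PressureSeries, fit_series

__all__ = [
    "GAS_CONSTANT",
    "TransitionThermo",
    "StateShift",
    "MultiStateModel",
    "deltaG",
    "populations",
    "ensemble_shift",
    "compression_correct",
    "fit_two_state",
    "TwoStateFit",
    "compressibility_ratio",
    "CompressibilityRatio",
]

GAS_CONSTANT = 8.314  # J / (mol K)


@dataclass(frozen=True)
class TransitionThermo:
    """Thermodynamics of one transition between consecutive states."""

    dG0: float          # kJ/mol at dP = 0
    dV0: float          # mL/mol
    dVdP: float = 0.0   # mL/mol/GPa == -delta beta'; 0 -> Delta G linear in P


def deltaG(t: TransitionThermo, dP) -> float:
    """ΔG(ΔP) in kJ/mol for a pressure offset ΔP in MPa."""
    dP = np.asarray(dP, dtype=float)
    out = t.dG0 + t.dV0 * dP / 1e3 + 0.5 * t.dVdP * dP**2 / 1e6
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StateShift:
    """Intrinsic shift parameters of one state for one observed atom."""

    delta0: float       # ppm
    b1: float = 0.0     # ppm / GPa
    b2: float = 0.0     # ppm / GPa^2


@dataclass
class MultiStateModel:
    """Chain-parameterized M-state fast-exchange model.

    ``transitions[i]`` describes state i+1 -> i+2, so
    ΔG_1j = Σ_{k<j} ΔG_{k,k+1}; the chain form keeps M-state fits
    identifiable.
    """

    transitions: list                       # list[TransitionThermo], len M-1
    state_shifts: dict = field(default_factory=dict)  # atom -> list[StateShift]
    temperature: float = 283.0              # K
    gas_constant: float = GAS_CONSTANT

    @property
    def n_states(self) -> int:
        return len(self.transitions) + 1

    @property
    def rt_kj(self) -> float:
        if self.temperature <= 0:
            raise UsageError("temperature must be positive")
        return self.gas_constant * self.temperature / 1e3


def populations(model: MultiStateModel, dP) -> np.ndarray:
    """Boltzmann state populations at ΔP (MPa); sums to 1 exactly.

    Computed in log space, so extreme ΔG values saturate cleanly to 0/1
    instead of overflowing.
    """
    rt = model.rt_kj
    dG_1j = np.concatenate(
        [[0.0], np.cumsum([deltaG(t, dP) for t in model.transitions])])
    log_w = -dG_1j / rt
    p = np.exp(log_w - logsumexp(log_w))
    return p / p.sum()


def ensemble_shift(model: MultiStateModel, atom: str, dP,
                   shared_compression: bool = False) -> float:
    """Population-weighted shift of ``atom`` at pressure offset ΔP (MPa).

    With ``shared_compression`` the per-state B coefficients are replaced
    by the first state's pair, giving exactly
    weighted-δ₀ + B₁ΔP + B₂ΔP².
    """
    try:
        states = model.state_shifts[atom]
    except KeyError:
        raise UsageError(f"no state shifts defined for atom {atom!r}") from None
    if len(states) != model.n_states:
        raise UsageError(
            f"{len(states)} state shifts for a {model.n_states}-state model")
    p = populations(model, dP)
    dp_gpa = np.asarray(dP, dtype=float) / 1e3
    if shared_compression:
        b1, b2 = states[0].b1, states[0].b2
        w_delta0 = sum(pj * s.delta0 for pj, s in zip(p, states))
        return float(w_delta0 + b1 * dp_gpa + b2 * dp_gpa**2)
    return float(sum(
        pj * (s.delta0 + s.b1 * dp_gpa + s.b2 * dp_gpa**2)
        for pj, s in zip(p, states)))


def compression_correct(series: PressureSeries, b1: float, b2: float,
                        p0: float = P0_DEFAULT) -> PressureSeries:
    """Subtract the compression polynomial B₁ΔP + B₂ΔP² from a series.

    With B fixed at the random-coil values this removes the state-shared
    compression response, leaving the population-weighted δ₀ term for the
    thermodynamic fit.  The point at P₀ is unchanged.
    """
    pts = []
    for pt in series.points:
        dp = (pt.pressure - p0) / 1e3
        pts.append(PressurePoint(pt.pressure,
                                 pt.shift - (b1 * dp + b2 * dp**2), pt.sigma))
    return PressureSeries(atom_id=series.atom_id, points=pts,
                          temperature=series.temperature)


@dataclass(frozen=True)
class TwoStateFit:
    thermo: TransitionThermo
    state1: StateShift
    state2: StateShift
    residual_sd: float          # ppm
    population_change: float    # |p2(max P) - p2(min P)|
    identifiability_warning: bool
    cost: float
    n_starts_converged: int


def _two_state_curve(theta, dp_mpa, b1, b2, rt, fit_dvdp):
    if fit_dvdp:
        dG0, dV0, d1, d2, dVdP = theta
    else:
        dG0, dV0, d1, d2 = theta
        dVdP = 0.0
    dG = dG0 + dV0 * dp_mpa / 1e3 + 0.5 * dVdP * dp_mpa**2 / 1e6
    # p2 = e^{-dG/RT} / (1 + e^{-dG/RT}), numerically safe sigmoid
    x = -dG / rt
    p2 = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                  np.exp(x) / (1.0 + np.exp(x)))
    dp_gpa = dp_mpa / 1e3
    return (1 - p2) * d1 + p2 * d2 + b1 * dp_gpa + b2 * dp_gpa**2


def fit_two_state(series: PressureSeries, b_shared, *, temperature=None,
                  n_starts: int = 16, seed: int = 20200622,
                  fit_dvdp: bool = False, p0: float = P0_DEFAULT) -> TwoStateFit:
    """Fit the two-state model with fixed shared compression coefficients.

    Nonlinear least squares over (ΔG⁰, ΔV⁰, δ₀₁, δ₀₂) — plus ∂ΔV⁰/∂P when
    ``fit_dvdp`` — with the compression pair ``b_shared`` held at the
    externally supplied (typically random-coil) values.  Multi-start from a
    deterministic stratified spread of initial guesses; the best converged
    start wins.

    Raises :class:`NonIdentifiableError` for flat series or when the fitted
    amplitude |δ₀₁ − δ₀₂| is indistinguishable from the residual noise, and
    flags (without failing) fits whose population change over the observed
    pressure range is below 5 percentage points.
    """
    if len(series) < 6:
        raise FitError(f"two-state fit needs >= 6 points, got {len(series)}")
    temperature = series.temperature if temperature is None else temperature
    rt = GAS_CONSTANT * temperature / 1e3  # kJ/mol
    b1, b2 = float(b_shared[0]), float(b_shared[1])
    dp = series.pressures - p0
    y = series.shifts

    y_detrended = y - (b1 * dp / 1e3 + b2 * (dp / 1e3) ** 2)
    span = float(y_detrended.max() - y_detrended.min())
    if span < 1e-12:
        raise NonIdentifiableError(
            "series is flat after compression correction; no transition "
            "amplitude to fit")

    lo_d, hi_d = y_detrended.min() - 2 * span, y_detrended.max() + 2 * span
    bounds_lo = [-50.0, -500.0, lo_d, lo_d]
    bounds_hi = [50.0, 500.0, hi_d, hi_d]
    if fit_dvdp:
        bounds_lo.append(-1e3)
        bounds_hi.append(1e3)

    rng = np.random.default_rng(seed)
    # Latin-hypercube-style spread: one stratum per start and parameter,
    # independently permuted
    n_par = len(bounds_lo)
    strata = (np.arange(n_starts) + 0.5) / n_starts
    u = np.column_stack([rng.permutation(strata) for _ in range(n_par)])
    start_lo = np.array([-10.0, -150.0, y_detrended.min(), y_detrended.min()]
                        + ([-200.0] if fit_dvdp else []))
    start_hi = np.array([10.0, 150.0, y_detrended.max(), y_detrended.max()]
                        + ([200.0] if fit_dvdp else []))
    starts = start_lo + u * (start_hi - start_lo)

    best = None
    n_ok = 0
    for theta0 in starts:
        try:
            res = least_squares(
                lambda th: _two_state_curve(th, dp, b1, b2, rt, fit_dvdp) - y,
                theta0, bounds=(bounds_lo, bounds_hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if not res.success:
            continue
        n_ok += 1
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("no multi-start converged")

    theta = best.x
    dG0, dV0, d1, d2 = theta[:4]
    dVdP = theta[4] if fit_dvdp else 0.0
    # the model is invariant under swapping the two states with dG -> -dG;
    # canonicalize to "state 1 dominates at ambient pressure" (dG0 >= 0)
    if dG0 < 0:
        dG0, dV0, dVdP = -dG0, -dV0, -dVdP
        d1, d2 = d2, d1
    n_par_eff = len(theta)
    dof = max(len(y) - n_par_eff, 1)
    residual_sd = math.sqrt(2 * best.cost / dof)

    if abs(d1 - d2) <= 3 * residual_sd:
        raise NonIdentifiableError(
            f"state shifts coincide within noise (|Δδ₀| = {abs(d1 - d2):.2e} "
            f"ppm vs residual sd {residual_sd:.2e} ppm)")

    thermo = TransitionThermo(dG0=float(dG0), dV0=float(dV0), dVdP=float(dVdP))
    model = MultiStateModel(transitions=[thermo], temperature=temperature)
    p_lo = populations(model, float(dp.min()))[1]
    p_hi = populations(model, float(dp.max()))[1]
    pop_change = abs(p_hi - p_lo)
    warn = pop_change < 0.05
    if warn:
        warnings.warn(
            f"population changes by only {100 * pop_change:.1f} percentage "
            "points over the pressure range; ΔG⁰ and ΔV⁰ are weakly "
            "identified", stacklevel=2)

    return TwoStateFit(
        thermo=thermo,
        state1=StateShift(delta0=float(d1), b1=b1, b2=b2),
        state2=StateShift(delta0=float(d2), b1=b1, b2=b2),
        residual_sd=residual_sd,
        population_change=float(pop_change),
        identifiability_warning=bool(warn),
        cost=float(best.cost),
        n_starts_converged=n_ok)


@dataclass(frozen=True)
class CompressibilityRatio:
    ratio: float                 # B2/B1, GPa^-1
    implied_half_dbeta_over_dv: float  # -(1/2) Δβ'/ΔV under |ΔG/2RT| << 1
    caveat: str


_CAVEAT = ("valid only for a two-state system with |ΔG/2RT| << 1; outside "
           "that regime B₂/B₁ is not a compressibility measure")


def compressibility_ratio(b1: float, b2: float) -> CompressibilityRatio:
    """Interpret B₂/B₁ as −½ Δβ′/ΔV (small-ΔG two-state limit)."""
    if b1 == 0:
        raise RatioUndefinedError("B2/B1 undefined for B1 = 0")
    ratio = b2 / b1
    return CompressibilityRatio(ratio=ratio,
                                implied_half_dbeta_over_dv=ratio,
                                caveat=_CAVEAT)
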