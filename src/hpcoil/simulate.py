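"""Deterministic synthetic pressure-series and coefficient-set generators.

These generators are the test bed for every fitting and scoring path: a
forward model (polynomial, two-state or chained multi-state) evaluated on
a pressure grid plus i.i.d. Gaussian noise.  The default grid mirrors the
experimental design of the reference measurements — a series from 1 to
200 MPa — and the default noise level of 0.002 ppm is a realistic
peak-position reproducibility for well-resolved 1D/HSQC peaks at 800 MHz.
The seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError
from .pressure import P0_DEFAULT, PolynomialFit, PressureSeries, evaluate_shift
from .thermo import MultiStateModel, StateShift, TransitionThermo, ensemble_shift

__all__ = ["SimulationSpec", "gen_series", "gen_reference_like_dataset",
           "DEFAULT_GRID"]

#: 1-200 MPa in 20 MPa steps (11 pressures), mirroring the measured series
DEFAULT_GRID = (1.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 140.0, 160.0,
                180.0, 200.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Fully specified forward simulation of one pressure series."""

    model: str                       # 'polynomial' | 'two_state' | 'multi_state'
    params: dict = field(default_factory=dict)
    pressures: tuple = DEFAULT_GRID  # MPa
    noise_sd: float = 0.0            # ppm
    seed: int = 0
    temperature: float = 283.0       # K
    p0: float = P0_DEFAULT           # MPa

    def __post_init__(self):
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")


def _polynomial_truth(spec):
    p = spec.params
    fit = PolynomialFit(delta0=p["delta0"], b1=p.get("b1", 0.0),
                        b2=p.get("b2", 0.0), b3=p.get("b3", 0.0),
                        degree=3 if p.get("b3") else 2, p0=spec.p0)
    return evaluate_shift(fit, np.asarray(spec.pressures, dtype=float))


def _multistate_truth(spec):
    p = spec.params
    transitions = [t if isinstance(t, TransitionThermo) else TransitionThermo(**t)
                   for t in p["transitions"]]
    states = [s if isinstance(s, StateShift) else StateShift(**s)
              for s in p["states"]]
    model = MultiStateModel(transitions=transitions,
                            state_shifts={"obs": states},
                            temperature=spec.temperature)
    shared = bool(p.get("shared_compression", True))
    return np.array([
        ensemble_shift(model, "obs", pr - spec.p0, shared_compression=shared)
        for pr in spec.pressures])


def gen_series(spec: SimulationSpec) -> PressureSeries:
    """Forward-model series on the grid plus seeded Gaussian noise.

    ``two_state`` expects params dG0, dV0 (dVdP optional), delta0_1,
    delta0_2 and the shared pair b1/b2; ``multi_state`` takes explicit
    ``transitions`` and ``states`` lists; ``polynomial`` takes delta0 and
    b1..b3.
    """
    if spec.model == "polynomial":
        truth = _polynomial_truth(spec)
    elif spec.model == "two_state":
        p = spec.params
        two = {
            "transitions": [TransitionThermo(dG0=p["dG0"], dV0=p["dV0"],
                                             dVdP=p.get("dVdP", 0.0))],
            "states": [StateShift(delta0=p["delta0_1"], b1=p.get("b1", 0.0),
                                  b2=p.get("b2", 0.0)),
                       StateShift(delta0=p["delta0_2"], b1=p.get("b1", 0.0),
                                  b2=p.get("b2", 0.0))],
            "shared_compression": True,
        }
        truth = _multistate_truth(SimulationSpec(
            model="multi_state", params=two, pressures=spec.pressures,
            temperature=spec.temperature, p0=spec.p0))
    elif spec.model == "multi_state":
        truth = _multistate_truth(spec)
    else:
        raise UsageError(f"unknown model {spec.model!r}")

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=len(truth)) \
        if spec.noise_sd > 0 else np.zeros(len(truth))
    return PressureSeries.from_arrays(
        np.asarray(spec.pressures, dtype=float), truth + noise,
        atom_id=("sim", spec.model, "-"), temperature=spec.temperature)


def gen_reference_like_dataset(seed: int, n: int = 200, *, rho: float = -0.8,
                               slope: float = -1.4, b1_mean: float = -0.05,
                               b1_sd: float = 0.06):
    """Synthetic coefficient table with a controlled B₁–B₂ correlation.

    B₁ is Gaussian; B₂ = slope·B₁ + ε with ε scaled so that the population
    Pearson correlation equals ``rho``.  ``rho = ±1`` collapses to an
    exact line; ``rho = 0`` makes B₂ independent of B₁ (the slope
    parameter is then irrelevant).  Returns a pandas DataFrame shaped like
    the packaged coefficient tables.
    """
    import pandas as pd

    if not -1.0 <= rho <= 1.0:
        raise UsageError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    b1 = rng.normal(b1_mean, b1_sd, size=n)
    signal_sd = abs(slope) * b1_sd
    if abs(rho) == 1.0:
        # deterministic line; its sign follows rho
        b2 = np.sign(rho) * abs(slope) * b1
    elif rho == 0.0:
        b2 = rng.normal(0.0, signal_sd, size=n)
    else:
        line = np.sign(rho) * abs(slope) * b1
        noise_sd = signal_sd * np.sqrt(1.0 / rho**2 - 1.0)
        b2 = line + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({
        "residue": ["Xaa"] * n,
        "atom": [f"HB{i}" for i in range(n)],
        "nucleus": ["1H"] * n,
        "delta0": np.round(rng.uniform(0.5, 4.5, size=n), 3),
        "b1": b1,
        "b2": b2,
    })
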