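"""Aggregate analyses of the reference coefficients and deviation scoring.

Two complementary summaries of the B₁–B₂ relationship are provided:

* grouping by *side-chain position* (Hβ, Hγ, ..., Nε) — resonances at the
  same bond distance from the backbone;
* grouping by *chemical group* (CH₃, CH₂, ring CH, amide NH₂, ...) —
  resonances attached to the same functional group.

For each group the ordinary-least-squares slope of B₂ on B₁ (with
intercept) estimates the common B₂/B₁ ratio far more robustly than the
mean of the per-atom ratios, whose individual errors can be enormous;
the Pearson correlation coefficient measures how well one common ratio
describes the group.  Measurement variants (Pro cis/trans, Cys red/ox,
His at two pH values) enter as separate atoms.

``random_coil_deviation`` scores an experimental pressure series against
the random-coil prediction; a series matching within noise across the
whole pressure range is evidence that the stretch of sequence is
disordered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UsageError
from .pressure import PressureSeries, fit_series

__all__ = [
    "CorrelationSummary",
    "ols_slope_and_r",
    "position_label",
    "chemical_group_label",
    "group_summary",
    "column_stats",
    "table_footer_stats",
    "DeviationScore",
    "random_coil_deviation",
]

_GREEK_POSITIONS = "ABGDEZH"  # alpha..eta in IUPAC atom-label order


@dataclass(frozen=True)
class CorrelationSummary:
    label: str
    n: int
    slope: float | None          # GPa^-1 (B2 on B1, with intercept)
    slope_ci95: float | None     # 95% half-width (t-distribution, n-2 dof)
    pearson_r: float | None
    intercept: float | None = None


def ols_slope_and_r(b1s, b2s, label: str = "") -> CorrelationSummary:
    """OLS slope (with intercept) and Pearson r of B₂ against B₁."""
    x = np.asarray(b1s, dtype=float)
    y = np.asarray(b2s, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("b1s and b2s must be 1-d arrays of equal length")
    n = len(x)
    if n < 2:
        raise UsageError("need at least 2 points for a slope")
    if np.ptp(x) == 0:
        raise UsageError("undefined slope: no variance in B1 values")
    res = stats.linregress(x, y)
    if n >= 3 and np.isfinite(res.stderr) and res.stderr > 0:
        ci = float(stats.t.ppf(0.975, n - 2) * res.stderr)
    else:
        ci = None
    return CorrelationSummary(label=label, n=n, slope=float(res.slope),
                              slope_ci95=ci, pearson_r=float(res.rvalue),
                              intercept=float(res.intercept))


def position_label(atom: str, nucleus: str) -> str:
    """Side-chain position label of an atom: HB, HG, ..., NE, HN, HA, N, C.

    Methyl pseudo-atoms count at the position of their carbon (QB → HB);
    backbone labels (HN/H, HA, N, C, CA) pass through unchanged.
    """
    atom = atom.upper()
    if atom in ("HN", "H"):
        return "HN"
    if atom in ("HA", "HA2", "HA3"):
        return "HA"
    if atom == "N":
        return "N"
    if atom in ("C", "C'"):
        return "C'"
    head, pos = atom[0], atom[1] if len(atom) > 1 else ""
    if head == "Q":
        head = "H" if nucleus == "1H" else head
    if pos in _GREEK_POSITIONS:
        return head + pos
    return atom


# chemical-group classification -------------------------------------------

_METHINE = {("Ile", "HB"), ("Thr", "HB"), ("Val", "HB"), ("Leu", "HG")}
_RING_CH_RES = {
    "His": {"HD2", "HE1"},
    "Phe": {"HD1", "HD2", "HE1", "HE2", "HZ"},
    "Tyr": {"HD1", "HD2", "HE1", "HE2"},
    "Trp": {"HD1", "HE3", "HZ2", "HZ3", "HH2"},
}
_AMIDE_H2N = {("Asn", "HD21"), ("Asn", "HD22"), ("Gln", "HE21"),
              ("Gln", "HE22"), ("Arg", "QH1"), ("Arg", "QH2")}
_N_AMIDE = {("Asn", "ND2"), ("Gln", "NE2"), ("Arg", "NH1"), ("Arg", "NH2")}
_N_RING = {("His", "ND1"), ("His", "NE2"), ("Trp", "NE1")}


def chemical_group_label(record) -> str:
    """Functional-group label of one coefficient record.

    Proton labels: H3C (methyl), H2C (methylene), HC (aliphatic methine),
    HC_ring (aromatic CH), H2N (amide/guanidino NH₂), H3N (NH₃⁺), HN_ring /
    HN (nitrogen-bound single protons).  Nitrogen labels: NH2 (primary
    amide/guanidino), N_ring, NH3, NH.
    """
    res, atom, nuc = record.residue, record.atom.upper(), record.nucleus
    if nuc == "15N":
        if (res, atom) in _N_AMIDE:
            return "NH2"
        if (res, atom) in _N_RING:
            return "N_ring"
        if atom == "NZ":
            return "NH3"
        return "NH"
    if nuc != "1H":
        return "C_" + atom  # companion carbon tables: keep coarse label
    if atom.startswith("Q"):
        if (res, atom) in _AMIDE_H2N:
            return "H2N"
        if atom == "QZ":
            return "H3N"
        return "H3C"
    if (res, atom) in _AMIDE_H2N:
        return "H2N"
    if atom in _RING_CH_RES.get(res, ()):
        return "HC_ring"
    if (res, atom) == ("Trp", "HE1"):
        return "HN_ring"
    if (res, atom) == ("Arg", "HE"):
        return "HN"
    if (res, atom) in _METHINE:
        return "HC"
    return "H2C"


def group_summary(db, mode: str = "by_position", *, include_h2n: bool = False):
    """One correlation summary per position / chemical-group label.

    Groups with a single member are reported with n=1 and no slope;
    empty selections cannot occur (every record maps to one label).

    By default the side-chain amide/guanidino NH₂ protons are kept out of
    the per-position groups: they form a chemically distinct class with
    its own H2N row in the chemical-group analysis, and the reference
    per-position atom counts are defined without them.  Set
    ``include_h2n=True`` to fold them in by Greek position instead.
    """
    if mode == "by_position":
        def labeller(rec):
            if not include_h2n and chemical_group_label(rec) == "H2N":
                return None
            return position_label(rec.atom, rec.nucleus)
    elif mode == "by_chemical_group":
        labeller = chemical_group_label
    else:
        raise UsageError("mode must be 'by_position' or 'by_chemical_group'")

    groups: dict[str, list] = {}
    for rec in db.records:
        label = labeller(rec)
        if label is None:
            continue
        groups.setdefault(label, []).append(rec)

    out = []
    for label in sorted(groups):
        recs = groups[label]
        b1 = [r.b1 for r in recs]
        b2 = [r.b2 for r in recs]
        if len(recs) < 2 or np.ptp(b1) == 0:
            warnings.warn(f"group {label!r}: n={len(recs)}, no regression",
                          stacklevel=2)
            out.append(CorrelationSummary(label=label, n=len(recs),
                                          slope=None, slope_ci95=None,
                                          pearson_r=None))
            continue
        out.append(ols_slope_and_r(b1, b2, label=label))
    return out


def column_stats(records, field: str) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n−1) of one coefficient column."""
    vals = [getattr(r, field) for r in records]
    vals = [v for v in vals if v is not None]
    if len(vals) < 2:
        raise UsageError(f"need >= 2 records with {field!r}, got {len(vals)}")
    arr = np.asarray(vals, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def table_footer_stats(db, source: str, nucleus: str | None = None) -> dict:
    """Recompute a table's footer (mean, sd) per column over printed rows.

    Records expanded from a single printed row (symmetric aromatic pairs)
    are counted once, matching the printed footers.
    """
    recs = db.select(source=source, nucleus=nucleus)
    if not recs:
        raise UsageError(f"no records with source={source!r}")
    seen, unique = set(), []
    for r in recs:
        key = (r.source, r.printed_row)
        if key in seen:
            continue
        seen.add(key)
        unique.append(r)
    out = {}
    for field in ("delta0", "b1", "b2", "ratio_printed"):
        try:
            out[field] = column_stats(unique, field)
        except UsageError:
            pass
    return out


@dataclass(frozen=True)
class DeviationScore:
    rms_over_noise: float        # offset-corrected RMS deviation / noise sd
    z_b1: float | None           # (fitted − reference) / 95% half-width
    z_b2: float | None
    random_coil_like: bool


def random_coil_deviation(series: PressureSeries, prediction, noise_sd: float,
                          reference=None, *, rms_threshold: float = 2.0,
                          z_threshold: float = 2.0) -> DeviationScore:
    """Score a measured series against a random-coil predicted curve.

    The RMS deviation is computed after removing the mean offset (a
    constant shift offset carries no pressure information) and divided by
    the stated noise level.  When a reference record is supplied, the
    series is additionally fitted and the fitted B₁/B₂ are expressed as
    z-scores against the reference record's 95% half-widths combined (in
    quadrature) with the fit's own 95% half-widths, so that a noisy but
    coefficient-consistent series is not flagged spuriously.  The
    thresholds (default 2) defining "random-coil-like" are package
    conventions, not part of the reference dataset.
    """
    pred = np.asarray(prediction, dtype=float)
    y = series.shifts
    if pred.shape != y.shape:
        raise UsageError(
            f"prediction length {pred.shape} does not match series "
            f"{y.shape}; evaluate the prediction on the series' pressures")
    if noise_sd <= 0:
        raise UsageError("noise_sd must be positive")
    resid = y - pred
    resid = resid - resid.mean()
    rms = float(np.sqrt(np.mean(resid**2))) / noise_sd

    z1 = z2 = None
    if reference is not None:
        fit = fit_series(series, degree=2)
        fit_hw = fit.ci95 if fit.ci95 is not None else np.zeros(3)
        hw1 = float(np.hypot(reference.err_b1, fit_hw[1]))
        hw2 = float(np.hypot(reference.err_b2, fit_hw[2]))
        z1 = float((fit.b1 - reference.b1) / hw1) if hw1 > 0 else np.inf
        z2 = float((fit.b2 - reference.b2) / hw2) if hw2 > 0 else np.inf

    ok = rms <= rms_threshold
    if z1 is not None:
        ok = ok and abs(z1) <= z_threshold and abs(z2) <= z_threshold
    return DeviationScore(rms_over_noise=rms, z_b1=z1, z_b2=z2,
                          random_coil_like=bool(ok))
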