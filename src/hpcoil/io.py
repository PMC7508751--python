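"""Delimited-text input, JSON/TSV output and run configuration.

Pressure-series tables are plain TSV/CSV with a header containing at
least ``residue``, ``atom``, ``pressure_MPa`` and ``shift_ppm`` (optional
``variant`` and ``sigma_ppm``); rows are grouped into one series per
(residue, atom, variant) and sorted by pressure.  Unicode minus signs are
normalized on input.  Outputs are JSON (fits, thermodynamic parameters)
or TSV (group summaries) with a provenance block carrying the package
version, configuration echo and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParseError, UsageError
from .pressure import PolynomialFit, PressurePoint, PressureSeries

__all__ = ["RunConfig", "read_series_table", "write_results", "read_results",
           "fit_to_dict", "fit_from_dict"]

_MINUS = str.maketrans({"−": "-", "–": "-", "—": "-"})
_REQUIRED = ("residue", "atom", "pressure_MPa", "shift_ppm")


@dataclass
class RunConfig:
    """Validated run-wide settings, echoed into every output file."""

    temperature: float = 283.0   # K
    p0: float = 0.1              # MPa
    pro_default: str = "pro:trans"
    cys_default: str = "cys:red"
    rms_threshold: float = 2.0   # random-coil deviation score
    z_threshold: float = 2.0
    precision: int = 6           # digits written to text outputs

    def __post_init__(self):
        if self.temperature <= 0:
            raise UsageError("temperature must be positive")
        if self.p0 <= 0:
            raise UsageError("p0 must be positive")
        if self.precision < 1:
            raise UsageError("precision must be >= 1")

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def read_series_table(path, temperature: float = 283.0) -> list[PressureSeries]:
    """Parse a delimited series table into one PressureSeries per atom."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").translate(_MINUS) for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not lines:
        raise ParseError("empty series table", file=path.name)
    delim = "\t" if "\t" in lines[0][1] else ","
    header = [c.strip() for c in lines[0][1].split(delim)]
    missing = [c for c in _REQUIRED if c not in header]
    if missing:
        raise ParseError(f"missing required column(s) {missing}",
                         file=path.name, line=lines[0][0])
    idx = {c: header.index(c) for c in header}

    groups: dict[tuple, list] = {}
    for lineno, ln in lines[1:]:
        cells = [c.strip() for c in ln.split(delim)]
        if len(cells) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, got {len(cells)}",
                file=path.name, line=lineno)

        def num(col, optional=False):
            if optional and (col not in idx or cells[idx[col]] in ("", ".")):
                return None
            try:
                return float(cells[idx[col]])
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cells[idx[col]]!r} in column "
                    f"{col!r}", file=path.name, line=lineno) from None

        key = (cells[idx["residue"]], cells[idx["atom"]],
               cells[idx["variant"]] if "variant" in idx and cells[idx["variant"]] not in ("", ".")
               else "-")
        groups.setdefault(key, []).append(
            PressurePoint(num("pressure_MPa"), num("shift_ppm"),
                          num("sigma_ppm", optional=True)))

    return [PressureSeries(atom_id=key, points=pts, temperature=temperature)
            for key, pts in groups.items()]


# ---------------------------------------------------------------------------
# result serialization


def _provenance(config=None, seed=None):
    from . import __version__

    block = {"package": "hpcoil", "version": __version__}
    if config is not None:
        block["config"] = asdict(config) if not isinstance(config, dict) else config
    if seed is not None:
        block["seed"] = seed
    return block


def fit_to_dict(fit: PolynomialFit) -> dict:
    return {
        "delta0": fit.delta0, "b1": fit.b1, "b2": fit.b2, "b3": fit.b3,
        "degree": fit.degree, "p0": fit.p0,
        "covariance": None if fit.covariance is None
        else np.asarray(fit.covariance).tolist(),
        "ci95": None if fit.ci95 is None else np.asarray(fit.ci95).tolist(),
        "residual_sd": fit.residual_sd, "n": fit.n,
    }


def fit_from_dict(d: dict) -> PolynomialFit:
    return PolynomialFit(
        delta0=d["delta0"], b1=d["b1"], b2=d["b2"], b3=d.get("b3", 0.0),
        degree=d["degree"], p0=d["p0"],
        covariance=None if d.get("covariance") is None
        else np.asarray(d["covariance"]),
        ci95=None if d.get("ci95") is None else np.asarray(d["ci95"]),
        residual_sd=d.get("residual_sd", 0.0), n=d.get("n", 0))


def write_results(results, path, fmt: str = "json", *, config=None, seed=None):
    """Write fits/summaries/scores round-trip-safely with provenance.

    ``fmt='json'`` accepts any JSON-serializable mapping/sequence (use
    :func:`fit_to_dict` for fits).  ``fmt='tsv'`` expects a sequence of
    flat mappings and writes them in column order of the first row
    (summaries mirror the reference-table layout: label, n, slope, ci, r).
    """
    path = Path(path)
    if fmt == "json":
        payload = {"provenance": _provenance(config, seed), "results": results}
        path.write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n",
                        encoding="utf-8")
    elif fmt == "tsv":
        rows = list(results)
        cols = list(rows[0].keys()) if rows else \
            ["label", "n", "slope", "slope_ci95", "pearson_r"]
        lines = ["\t".join(cols)]
        for row in rows:
            lines.append("\t".join(_cell(row.get(c)) for c in cols))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise UsageError(f"unknown format {fmt!r}")


def read_results(path) -> dict:
    """Read back a JSON results file written by :func:`write_results`."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def _cell(v):
    if v is None:
        return "."
    if isinstance(v, float):
        return repr(v)
    return str(v)
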