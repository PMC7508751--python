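"""Reference database of random-coil side-chain pressure coefficients.

The packaged tables hold, for every side-chain ¹H and ¹⁵N resonance of the
residue X in the protected tetrapeptide Ac-Gly-Gly-X-Ala-NH₂ at 283 K and
pH 6.7 (His additionally at pH 4.0 and 8.5), the chemical shift at ambient
pressure δ₀ together with the first- and second-order pressure coefficients
B₁ (ppm·GPa⁻¹) and B₂ (ppm·GPa⁻²) of the Taylor expansion

    δ(P) = δ₀ + B₁ (P − P₀) + B₂ (P − P₀)²,      P₀ = 0.1 MPa,

their 95%-confidence half-widths, and the printed B₂/B₁ ratio.  A companion
table lists the deuterium/¹³C/¹⁵N isotope shifts measured on stereo-array
isotope labeled (SAIL) amino acids that anchor the stereospecific
assignments, and a correction table holds the sequence-neighbor corrections
served by :mod:`hpcoil.corrections`.

Geminal methylene pairs appear in four flavours, recorded in
``stereo_status``:

* ``stereospecific`` – the two resonances are assigned to Hβ2/Hβ3 etc.
* ``tentative`` – assignment transferred from the free SAIL amino acid.
* ``ambiguous`` – two distinct resonances whose stereo assignment is open;
  the labels HB2/HB3 follow the printed (upfield-first) order and are
  interchangeable.
* ``degenerate`` – a single resonance for both protons (or a symmetric
  aromatic pair); the record is duplicated under both labels with identical
  numbers.

Methyl (and other magnetically equivalent) groups are stored under
pseudo-atom labels (QB, QG1, QD1, QE, QZ, QH1, ...) with an alias map from
the per-proton IUPAC names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import AmbiguityError, NotComputableError, NotFoundError, RefDataError

__all__ = [
    "CoefficientRecord",
    "IsotopeShiftRecord",
    "ReferenceDatabase",
    "load_reference",
    "lookup",
    "isotope_shift",
    "AA3_TO_1",
    "AA1_TO_3",
    "normalize_residue",
    "resolve_atom_alias",
]

# one <-> three letter amino acid codes -------------------------------------

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: per-proton IUPAC names -> pseudo-atom label of the equivalent group
_ATOM_ALIASES = {
    ("Ala", "HB1"): "QB", ("Ala", "HB2"): "QB", ("Ala", "HB3"): "QB",
    ("Ala", "MB"): "QB",
    ("Ile", "HG21"): "QG2", ("Ile", "HG22"): "QG2", ("Ile", "HG23"): "QG2",
    ("Ile", "HD11"): "QD1", ("Ile", "HD12"): "QD1", ("Ile", "HD13"): "QD1",
    ("Leu", "HD11"): "QD1", ("Leu", "HD12"): "QD1", ("Leu", "HD13"): "QD1",
    ("Leu", "HD21"): "QD2", ("Leu", "HD22"): "QD2", ("Leu", "HD23"): "QD2",
    ("Val", "HG11"): "QG1", ("Val", "HG12"): "QG1", ("Val", "HG13"): "QG1",
    ("Val", "HG21"): "QG2", ("Val", "HG22"): "QG2", ("Val", "HG23"): "QG2",
    ("Thr", "HG21"): "QG2", ("Thr", "HG22"): "QG2", ("Thr", "HG23"): "QG2",
    ("Met", "HE1"): "QE", ("Met", "HE2"): "QE", ("Met", "HE3"): "QE",
    ("Lys", "HZ1"): "QZ", ("Lys", "HZ2"): "QZ", ("Lys", "HZ3"): "QZ",
    ("Arg", "HH11"): "QH1", ("Arg", "HH12"): "QH1",
    ("Arg", "HH21"): "QH2", ("Arg", "HH22"): "QH2",
}

_STEREO_STATES = {"stereospecific", "tentative", "ambiguous", "degenerate"}
_KNOWN_TAGS = {"pH:4.0", "pH:6.7", "pH:8.5", "pro:cis", "pro:trans",
               "cys:red", "cys:ox"}

_PACKAGED_FILES = {
    "tab2": "table2_hbeta.tsv",
    "tab3": "table3_sidechain_h.tsv",
    "tab4": "table4_nitrogen.tsv",
}
_ISOTOPE_FILE = "table1_isotope_shifts.tsv"
_CORRECTION_FILE = "table5_neighbor_corrections.tsv"

# U+2212 and friends -> ASCII minus; applied to every cell read from disk
_MINUS_TRANSLATION = str.maketrans({"−": "-", "–": "-", "—": "-"})


def normalize_residue(residue: str) -> str:
    """Return the three-letter code for a one- or three-letter residue name."""
    r = residue.strip()
    if len(r) == 1:
        try:
            return AA1_TO_3[r.upper()]
        except KeyError:
            raise NotFoundError(f"unknown amino acid code {residue!r}") from None
    r = r.capitalize()
    if r not in AA3_TO_1:
        raise NotFoundError(f"unknown amino acid code {residue!r}")
    return r


def resolve_atom_alias(residue: str, atom: str) -> str:
    """Map a per-proton IUPAC name of an equivalent group to its pseudo-atom."""
    atom = atom.strip().upper()
    return _ATOM_ALIASES.get((residue, atom), atom)


@dataclass(frozen=True)
class CoefficientRecord:
    """One table row: pressure-response parameters of a single resonance."""

    residue: str                 # three-letter code
    atom: str                    # IUPAC label, Q* for equivalent groups
    nucleus: str                 # '1H' | '15N' (schema also accepts '13C')
    delta0: float                # ppm at P0 = 0.1 MPa
    b1: float                    # ppm / GPa
    err_b1: float                # 95% confidence half-width
    b2: float                    # ppm / GPa^2
    err_b2: float                # 95% confidence half-width
    ratio_printed: float | None  # B2/B1 as printed, GPa^-1
    err_ratio_printed: float | None
    ratio_bracketed: bool        # printed in brackets (error >= |value|)
    stereo_status: str
    variant: frozenset = field(default_factory=frozenset)
    source: str = ""
    printed_row: int | None = None  # shared by records expanded from one row

    @property
    def key(self):
        return (self.residue, self.atom, self.variant)

    def variant_str(self) -> str:
        return ",".join(sorted(self.variant)) or "-"


@dataclass(frozen=True)
class IsotopeShiftRecord:
    """δ₀ of one resonance in the SAIL vs. the unlabeled amino acid."""

    residue: str
    atom: str
    delta_sail: float | None     # ppm; None when not detected
    delta_unlabeled: float | None
    weak_signal: bool            # SAIL value from residual protonation
    diff: float | None           # printed upfield isotope shift, ppm
    variant: frozenset = field(default_factory=frozenset)


def isotope_shift(rec: IsotopeShiftRecord) -> float:
    """Isotope shift Δδ₀ = δ₀(unlabeled) − δ₀(SAIL), rounded to 3 decimals."""
    if rec.delta_sail is None or rec.delta_unlabeled is None:
        raise NotComputableError(
            f"{rec.residue} {rec.atom}: one of the two shifts was not detected")
    return round(rec.delta_unlabeled - rec.delta_sail, 3)


class ReferenceDatabase:
    """Queryable collection of coefficient, isotope and correction records."""

    def __init__(self, records, isotope_records, correction_table):
        self.records = list(records)
        self.isotope_records = list(isotope_records)
        self.correction_table = correction_table
        self._index: dict = {}
        for rec in self.records:
            if rec.key in self._index:
                raise RefDataError(
                    f"duplicate record key {rec.key}", file=rec.source)
            self._index[rec.key] = rec

    def __len__(self):
        return len(self.records)

    def select(self, *, residue=None, atom=None, nucleus=None, source=None):
        """Filter records; any criterion left as None matches everything."""
        out = []
        res3 = normalize_residue(residue) if residue else None
        for rec in self.records:
            if res3 and rec.residue != res3:
                continue
            if atom and rec.atom != atom.upper():
                continue
            if nucleus and rec.nucleus != nucleus:
                continue
            if source and rec.source != source:
                continue
            out.append(rec)
        return out

    def lookup(self, residue, atom, variant=None) -> CoefficientRecord:
        return lookup(self, residue, atom, variant)

    def to_frame(self):
        """All coefficient records as a pandas DataFrame (analysis helper)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "residue": r.residue,
                "atom": r.atom,
                "nucleus": r.nucleus,
                "variant": r.variant_str(),
                "delta0": r.delta0,
                "b1": r.b1,
                "err_b1": r.err_b1,
                "b2": r.b2,
                "err_b2": r.err_b2,
                "ratio": r.ratio_printed,
                "err_ratio": r.err_ratio_printed,
                "stereo_status": r.stereo_status,
                "printed_row": r.printed_row,
                "source": r.source,
            }
            for r in self.records
        )


def lookup(db: ReferenceDatabase, residue, atom, variant=None) -> CoefficientRecord:
    """Find the unique coefficient record for (residue, atom, variant tags).

    When several measurement variants exist, the defaults are: Pro → trans
    isomer, Cys → reduced form.  His was measured at two pH values and has
    no defensible default, so an explicit ``pH:...`` tag is required there.
    """
    res3 = normalize_residue(residue)
    atom = resolve_atom_alias(res3, atom)
    tags = frozenset([variant] if isinstance(variant, str) else (variant or ()))
    unknown = tags - _KNOWN_TAGS
    if unknown:
        raise NotFoundError(f"unknown variant tags {sorted(unknown)}")

    candidates = [r for r in db.records
                  if r.residue == res3 and r.atom == atom and tags <= r.variant]
    if not candidates:
        raise NotFoundError(
            f"no reference record for ({res3}, {atom}"
            + (f", {sorted(tags)}" if tags else "") + ")")
    if len(candidates) == 1:
        return candidates[0]

    # several variants left: apply defaults, His deliberately excluded
    if res3 == "Pro":
        trans = [r for r in candidates if "pro:trans" in r.variant]
        if len(trans) == 1:
            return trans[0]
    if res3 == "Cys":
        red = [r for r in candidates if "cys:red" in r.variant]
        if len(red) == 1:
            return red[0]
    raise AmbiguityError(
        f"({res3}, {atom}) is ambiguous; specify one of the variants "
        f"{sorted(r.variant_str() for r in candidates)}",
        variants=[r.variant_str() for r in candidates])


# ---------------------------------------------------------------------------
# loading & validation


def _cells(line):
    return [c.strip() for c in line.rstrip("\n").translate(_MINUS_TRANSLATION).split("\t")]


def _read_tsv(path: Path):
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise RefDataError("empty table", file=path.name)
    header = _cells(lines[0])
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = _cells(ln)
        if len(cells) != len(header):
            raise RefDataError(
                f"expected {len(header)} columns, got {len(cells)}",
                file=path.name, row=i)
        rows.append((i, dict(zip(header, cells))))
    return rows


def _fnum(raw, *, file, row, field_):
    if raw in (".", "", "-"):
        return None
    try:
        return float(raw)
    except ValueError:
        raise RefDataError(f"not a number: {raw!r}", file=file,
                           row=row, field=field_) from None


def _parse_variant(raw):
    if raw in (".", "", "-"):
        return frozenset()
    tags = frozenset(t.strip() for t in raw.split(","))
    return tags


_DELTA0_RANGE = {"1H": (-1.0, 12.0), "15N": (20.0, 200.0), "13C": (0.0, 220.0)}


def _load_coefficients(path: Path):
    records = []
    for rownum, row in _read_tsv(path):
        def num(col, required=True):
            v = _fnum(row.get(col, "."), file=path.name, row=rownum, field_=col)
            if v is None and required:
                raise RefDataError("missing value", file=path.name,
                                   row=rownum, field=col)
            return v

        residue = normalize_residue(row["residue"])
        nucleus = row["nucleus"]
        if nucleus not in _DELTA0_RANGE:
            raise RefDataError(f"unknown nucleus {nucleus!r}", file=path.name,
                               row=rownum, field="nucleus")
        stereo = row["stereo_status"]
        if stereo not in _STEREO_STATES:
            raise RefDataError(f"unknown stereo_status {stereo!r}",
                               file=path.name, row=rownum, field="stereo_status")
        variant = _parse_variant(row.get("variant", "."))
        if not variant <= _KNOWN_TAGS:
            raise RefDataError(f"unknown variant tags {sorted(variant - _KNOWN_TAGS)}",
                               file=path.name, row=rownum, field="variant")
        printed_row = row.get("printed_row")
        rec = CoefficientRecord(
            residue=residue,
            atom=row["atom"].upper(),
            nucleus=nucleus,
            delta0=num("delta0"),
            b1=num("b1"),
            err_b1=num("err_b1"),
            b2=num("b2"),
            err_b2=num("err_b2"),
            ratio_printed=num("ratio", required=False),
            err_ratio_printed=num("err_ratio", required=False),
            ratio_bracketed=row.get("bracketed", "n") == "y",
            stereo_status=stereo,
            variant=variant,
            source=row.get("source", path.stem),
            printed_row=int(printed_row) if printed_row not in (None, ".", "") else rownum,
        )
        _validate_coefficient(rec, path.name, rownum)
        records.append(rec)
    return records


def _validate_coefficient(rec: CoefficientRecord, fname, rownum):
    for fieldname in ("delta0", "b1", "b2"):
        if not math.isfinite(getattr(rec, fieldname)):
            raise RefDataError("non-finite value", file=fname, row=rownum,
                               field=fieldname)
    if rec.err_b1 < 0 or rec.err_b2 < 0:
        raise RefDataError("negative confidence half-width", file=fname,
                           row=rownum, field="err_b1/err_b2")
    lo, hi = _DELTA0_RANGE[rec.nucleus]
    if not lo <= rec.delta0 <= hi:
        raise RefDataError(
            f"delta0={rec.delta0} outside [{lo}, {hi}] ppm for {rec.nucleus}",
            file=fname, row=rownum, field="delta0")
    if rec.residue == "Gly" and rec.atom.startswith(("HB", "QB")):
        raise RefDataError("glycine has no beta proton", file=fname,
                           row=rownum, field="atom")
    # printed ratio must agree with b2/b1 within the precision the table
    # itself allows: the printed ratio was computed from unrounded
    # coefficients, so half an ulp of B1 and B2 propagates into it
    if rec.ratio_printed is not None and rec.b1 != 0:
        ulp_b1 = 0.5 * 10 ** -_decimals(rec.b1)
        ulp_b2 = 0.5 * 10 ** -_decimals(rec.b2)
        tol = ((ulp_b2 + abs(rec.ratio_printed) * ulp_b1) / abs(rec.b1)
               + 0.6 * 10 ** -_decimals(rec.ratio_printed))
        if abs(rec.b2 / rec.b1 - rec.ratio_printed) > tol:
            raise RefDataError(
                f"ratio {rec.ratio_printed} inconsistent with "
                f"b2/b1 = {rec.b2 / rec.b1:.3f}", file=fname, row=rownum,
                field="ratio")


def _decimals(x: float) -> int:
    s = f"{x}"
    return len(s.split(".")[1]) if "." in s else 0


def _load_isotope(path: Path):
    records = []
    for rownum, row in _read_tsv(path):
        sail = _fnum(row["delta_sail"], file=path.name, row=rownum,
                     field_="delta_sail")
        unl = _fnum(row["delta_unlabeled"], file=path.name, row=rownum,
                    field_="delta_unlabeled")
        diff = _fnum(row["diff"], file=path.name, row=rownum, field_="diff")
        rec = IsotopeShiftRecord(
            residue=normalize_residue(row["residue"]),
            atom=row["atom"].upper(),
            delta_sail=sail,
            delta_unlabeled=unl,
            weak_signal=row.get("sail_weak", "n") == "y",
            diff=diff,
            variant=_parse_variant(row.get("variant", ".")),
        )
        if rec.diff is not None:
            if rec.diff < 0:
                raise RefDataError("isotope shift must be upfield (diff >= 0)",
                                   file=path.name, row=rownum, field="diff")
            recomputed = isotope_shift(rec)
            if abs(recomputed - rec.diff) > 5e-4:
                raise RefDataError(
                    f"printed diff {rec.diff} != recomputed {recomputed}",
                    file=path.name, row=rownum, field="diff")
        records.append(rec)
    return records


def _check_database(db: ReferenceDatabase):
    hbeta = [r for r in db.records if r.source == "tab2"]
    if len(hbeta) != 40:
        raise RefDataError(f"Hbeta table must hold 40 records, got {len(hbeta)}")
    tab4_n = [r for r in db.records if r.source == "tab4" and r.nucleus == "15N"]
    tab4_h = [r for r in db.records if r.source == "tab4" and r.nucleus == "1H"]
    if len(tab4_n) != 9 or len(tab4_h) != 9:
        raise RefDataError(
            f"nitrogen table must hold 9+9 records, got {len(tab4_n)}+{len(tab4_h)}")
    # degenerate pairs carry identical numbers
    by_group: dict = {}
    for r in db.records:
        if r.stereo_status == "degenerate":
            by_group.setdefault((r.source, r.residue, r.variant, r.atom[:2]),
                                []).append(r)
    for group in by_group.values():
        first = group[0]
        for other in group[1:]:
            if (other.delta0, other.b1, other.b2) != (first.delta0, first.b1,
                                                      first.b2):
                raise RefDataError(
                    f"degenerate pair {first.residue} {first.atom}/{other.atom} "
                    "differs numerically", file=first.source)


def load_reference(data_dir=None) -> ReferenceDatabase:
    """Load the packaged reference tables (or a directory of compatible TSVs).

    ``data_dir`` defaults to the data shipped with the package.  A custom
    directory must contain the canonical five tables; additional coefficient
    tables named ``extra_*.tsv`` with the same schema (e.g. backbone ¹H/¹⁵N/¹³C
    coefficients from companion datasets) are loaded as well, keyed by their
    ``source`` column.
    """
    from .corrections import load_correction_table  # local import, no cycle at module load

    if data_dir is None:
        base = resources.files("hpcoil") / "data"
        data_dir = Path(str(base))
    else:
        data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise RefDataError(f"data directory {data_dir} does not exist")

    records = []
    for source, fname in _PACKAGED_FILES.items():
        path = data_dir / fname
        if not path.is_file():
            raise RefDataError("required table missing", file=fname)
        records.extend(_load_coefficients(path))
    for extra in sorted(data_dir.glob("extra_*.tsv")):
        records.extend(_load_coefficients(extra))

    iso_path = data_dir / _ISOTOPE_FILE
    if not iso_path.is_file():
        raise RefDataError("required table missing", file=_ISOTOPE_FILE)
    isotope_records = _load_isotope(iso_path)

    corr_path = data_dir / _CORRECTION_FILE
    if not corr_path.is_file():
        raise RefDataError("required table missing", file=_CORRECTION_FILE)
    correction_table = load_correction_table(corr_path)

    db = ReferenceDatabase(records, isotope_records, correction_table)
    _check_database(db)
    return db
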