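"""Sequence-neighbor corrections of random-coil pressure coefficients.

The pressure coefficients of a residue x in a peptide depend on its
sequence neighbors.  Correction factors C₁,₂ were derived from the
tetrapeptide series by differencing against the all-glycine reference:

    C₁,₂^(−1,a)(y) = B₁,₂^a(Ac-GGyA-NH₂) − B₁,₂^a(Ac-GGGA-NH₂)

read off the Ala4 reporter (and the Gly2/Gly1 reporters for the +1/+2
offsets).  Applying them to a residue x in the context -u x y z- is
additive:

    B₁,₂^corr(x) = B₁,₂(x) + C₁,₂^(−1)(u) + C₁,₂^(+1)(y) + C₁,₂^(+2)(z)

Corrections exist for the amide proton HN and Hα of any residue and for
the Ala β-methyl (offset −1 only).  Neighbors beyond the chain or replaced
by capping groups contribute zero, mirroring the glycine reference
construction.  Only the *pressure coefficients* are corrected: the
ambient-pressure shift δ₀ always comes from the reference record, because
the underlying dataset quotes δ₀ neighbor effects only as means, not as a
usable per-residue table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import NotFoundError, RefDataError, UsageError
from .pressure import P0_DEFAULT, PolynomialFit, evaluate_shift

__all__ = [
    "CorrectionRecord",
    "CorrectionTable",
    "SequenceContext",
    "load_correction_table",
    "derive_correction",
    "neighbor_correction",
    "corrected_coefficients",
    "CorrectedCoefficients",
    "predict_random_coil_curve",
]

_OFFSETS = (-1, +1, +2)
_CORR_ATOMS = ("HN", "HA", "HB_ALA")
_CAPS = {"acetyl", "amide", "free", "none"}


@dataclass(frozen=True)
class CorrectionRecord:
    """C₁/C₂ of one (neighbor residue, offset, reporter atom) combination."""

    neighbor: str        # three-letter code of the perturbing residue y
    offset: int          # -1, +1 or +2 relative to the target
    atom: str            # 'HN' | 'HA' | 'HB_ALA'
    c1: float            # ppm / GPa
    c2: float            # ppm / GPa^2
    variant: frozenset = field(default_factory=frozenset)


class CorrectionTable:
    """Lookup of neighbor corrections; Gly (and absent neighbors) are zero."""

    def __init__(self, records):
        self.records = list(records)
        self._index = {}
        self._columns = set()
        for rec in self.records:
            key = (rec.neighbor, rec.atom, rec.offset)
            if key in self._index:
                raise RefDataError(f"duplicate correction {key}")
            self._index[key] = rec
            self._columns.add((rec.atom, rec.offset))

    def __len__(self):
        return len(self.records)

    def has_atom(self, atom: str) -> bool:
        return any(r.atom == atom for r in self.records)

    def get(self, neighbor: str, atom: str, offset: int) -> tuple[float, float]:
        """(C1, C2) for one neighbor; absent/capped neighbors give (0, 0)."""
        from .refdata import normalize_residue

        if neighbor is None:
            return (0.0, 0.0)
        if (atom, offset) not in self._columns:
            # offsets without any data (e.g. HB_ALA beyond -1) are silently
            # zero, mirroring the tetrapeptide design
            return (0.0, 0.0)
        key = (normalize_residue(neighbor), atom, offset)
        try:
            rec = self._index[key]
        except KeyError:
            raise NotFoundError(
                f"no correction for neighbor={key[0]} atom={atom} "
                f"offset={offset:+d}") from None
        return (rec.c1, rec.c2)

    def column_mean(self, atom: str, offset: int, coefficient: int = 1) -> float:
        """Mean of one correction column over all 20 neighbor rows.

        The all-zero Gly row is part of the average, matching the printed
        table footer.
        """
        vals = [r.c1 if coefficient == 1 else r.c2
                for r in self.records if r.atom == atom and r.offset == offset]
        if not vals:
            raise UsageError(f"no corrections for atom={atom} offset={offset:+d}")
        return float(np.mean(vals))


def load_correction_table(path) -> CorrectionTable:
    """Read a correction TSV (columns neighbor/variant/atom/offset/c1/c2)."""
    from .refdata import _read_tsv, _fnum, _parse_variant, normalize_residue

    path = Path(path)
    records = []
    for rownum, row in _read_tsv(path):
        atom = row["atom"].upper()
        if atom not in _CORR_ATOMS:
            raise RefDataError(f"unknown correction atom {atom!r}",
                               file=path.name, row=rownum, field="atom")
        offset = int(row["offset"])
        if offset not in _OFFSETS:
            raise RefDataError(f"offset must be one of {_OFFSETS}",
                               file=path.name, row=rownum, field="offset")
        if atom == "HB_ALA" and offset != -1:
            raise RefDataError("HB_ALA corrections exist only for offset -1",
                               file=path.name, row=rownum, field="offset")
        c1 = _fnum(row["c1"], file=path.name, row=rownum, field_="c1")
        c2 = _fnum(row["c2"], file=path.name, row=rownum, field_="c2")
        if c1 is None or c2 is None:
            raise RefDataError("missing correction value", file=path.name,
                               row=rownum)
        neighbor = normalize_residue(row["neighbor"])
        if neighbor == "Gly" and (c1 != 0 or c2 != 0):
            raise RefDataError("the Gly reference row must be exactly zero",
                               file=path.name, row=rownum)
        records.append(CorrectionRecord(
            neighbor=neighbor, offset=offset, atom=atom, c1=c1, c2=c2,
            variant=_parse_variant(row.get("variant", "."))))
    return CorrectionTable(records)


@dataclass(frozen=True)
class SequenceContext:
    """A target position inside a peptide sequence (one-letter codes)."""

    sequence: str
    index: int                    # 0-based target position
    n_term_cap: str = "free"      # {'acetyl', 'amide', 'free', 'none'}
    c_term_cap: str = "free"

    def __post_init__(self):
        if not 0 <= self.index < len(self.sequence):
            raise UsageError(
                f"index {self.index} outside sequence of length "
                f"{len(self.sequence)}")
        if self.n_term_cap not in _CAPS or self.c_term_cap not in _CAPS:
            raise UsageError(f"caps must be one of {sorted(_CAPS)}")

    def neighbor(self, offset: int) -> str | None:
        """One-letter code at index+offset, or None beyond the chain/caps."""
        j = self.index + offset
        if 0 <= j < len(self.sequence):
            return self.sequence[j]
        return None


def derive_correction(b_variant, b_reference, *, neighbor, offset, atom
                      ) -> CorrectionRecord:
    """Difference two reporter coefficient pairs into a correction record.

    ``b_variant`` and ``b_reference`` are (B1, B2) pairs — or objects with
    ``b1``/``b2`` attributes — for the *same* reporter atom in the
    perturbed (Ac-GGyA-NH₂) and in the all-Gly reference peptide.
    """
    bv = _as_pair(b_variant)
    br = _as_pair(b_reference)
    for obj_a, obj_b, what in ((b_variant, b_reference, "residue"),
                               (b_variant, b_reference, "atom")):
        va, vb = getattr(obj_a, what, None), getattr(obj_b, what, None)
        if va is not None and vb is not None and va != vb:
            raise UsageError(
                f"reporter mismatch: variant has {what}={va}, reference "
                f"has {what}={vb}")
    if offset not in _OFFSETS:
        raise UsageError(f"offset must be one of {_OFFSETS}")
    from .refdata import normalize_residue

    return CorrectionRecord(
        neighbor=normalize_residue(neighbor), offset=offset, atom=atom,
        c1=bv[0] - br[0], c2=bv[1] - br[1])


def _as_pair(obj):
    if hasattr(obj, "b1"):
        return (float(obj.b1), float(obj.b2))
    b1, b2 = obj
    return (float(b1), float(b2))


def neighbor_correction(table: CorrectionTable, atom: str,
                        context: SequenceContext) -> tuple[float, float]:
    """Summed (C1, C2) for the three context neighbors of a target position.

    Corrections are additive and order-independent across the offsets;
    missing neighbors (chain ends, capping groups) contribute zero.
    """
    atom = atom.upper()
    c1 = c2 = 0.0
    for offset in _OFFSETS:
        nb = context.neighbor(offset)
        if nb is None:
            continue
        d1, d2 = table.get(nb, atom, offset)
        c1 += d1
        c2 += d2
    return (c1, c2)


@dataclass(frozen=True)
class CorrectedCoefficients:
    b1: float
    b2: float
    corrected: bool      # False when no correction table exists for the atom
    c1: float = 0.0
    c2: float = 0.0


def _correction_atom(residue3: str, atom: str) -> str | None:
    """Correction-table column for a (residue, atom), or None if uncovered."""
    atom = atom.upper()
    if atom in ("HN", "H"):
        return "HN"
    if atom == "HA":
        return "HA"
    if residue3 == "Ala" and atom in ("QB", "HB"):
        return "HB_ALA"
    return None


def corrected_coefficients(db, residue, atom, context: SequenceContext,
                           *, variant=None, base=None) -> CorrectedCoefficients:
    """Sequence-corrected (B1, B2) for residue ``x`` in its context.

    ``base`` overrides the reference-database lookup with an explicit
    (B1, B2) pair — needed e.g. for backbone atoms whose base coefficients
    come from a companion dataset.  Atoms without a correction table return
    the base values unchanged with ``corrected=False``.
    """
    from .refdata import normalize_residue

    res3 = normalize_residue(residue)
    if res3 == "Pro" and atom.upper() in ("HN", "H"):
        raise NotFoundError("proline has no amide proton")
    if base is not None:
        b1, b2 = _as_pair(base)
    else:
        rec = db.lookup(res3, atom, variant)
        b1, b2 = rec.b1, rec.b2

    corr_atom = _correction_atom(res3, atom)
    if corr_atom is None:
        import warnings

        warnings.warn(
            f"no neighbor-correction table for atom {atom!r}; returning "
            "uncorrected coefficients", stacklevel=2)
        return CorrectedCoefficients(b1=b1, b2=b2, corrected=False)
    table = db.correction_table if db is not None else None
    if table is None:
        raise UsageError("no correction table available")
    c1, c2 = neighbor_correction(table, corr_atom, context)
    return CorrectedCoefficients(b1=b1 + c1, b2=b2 + c2, corrected=True,
                                 c1=c1, c2=c2)


def predict_random_coil_curve(db, sequence: str, index: int, atom: str,
                              pressures, *, variant=None,
                              n_term_cap="acetyl", c_term_cap="amide",
                              p0: float = P0_DEFAULT):
    """Random-coil shift vs. pressure for one atom in a given sequence.

    δ₀ is taken from the reference record; B₁/B₂ are sequence-corrected
    when a correction table covers the atom.  Returns ``(shifts,
    corrected)`` where ``shifts`` is an ndarray of ppm values at the
    requested pressures (MPa).
    """
    pressures = np.atleast_1d(np.asarray(pressures, dtype=float))
    if pressures.size == 0:
        raise UsageError("pressure list is empty")
    context = SequenceContext(sequence=sequence, index=index,
                              n_term_cap=n_term_cap, c_term_cap=c_term_cap)
    rec = db.lookup(sequence[index], atom, variant)
    import warnings as _warnings

    corr_atom = _correction_atom(rec.residue, atom)
    if corr_atom is None:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            cc = CorrectedCoefficients(b1=rec.b1, b2=rec.b2, corrected=False)
    else:
        cc = corrected_coefficients(db, rec.residue, atom, context,
                                    variant=variant,
                                    base=(rec.b1, rec.b2))
    fit = PolynomialFit(delta0=rec.delta0, b1=cc.b1, b2=cc.b2, degree=2, p0=p0)
    return evaluate_shift(fit, pressures), cc.corrected
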