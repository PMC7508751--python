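"""Sequence-neighbor corrections: derivation, application, prediction."""

import numpy as np
import pytest

import hpcoil as hp
from hpcoil.corrections import (
    CorrectionRecord,
    CorrectionTable,
    SequenceContext,
    corrected_coefficients,
    derive_correction,
    neighbor_correction,
    predict_random_coil_curve,
)
from hpcoil.pressure import PolynomialFit, evaluate_shift
from hpcoil.refdata import AA1_TO_3


class TestTable:
    def test_gly_rows_are_zero(self, db):
        for atom, offset in [("HN", -1), ("HN", 1), ("HA", 2), ("HB_ALA", -1)]:
            assert db.correction_table.get("Gly", atom, offset) == (0.0, 0.0)

    def test_printed_column_means(self, db):
        ct = db.correction_table
        # first-order (C1) means, HN then HA rows of the table footer
        assert ct.column_mean("HN", -1) == pytest.approx(0.08, abs=0.005)
        assert ct.column_mean("HN", +1) == pytest.approx(0.01, abs=0.005)
        assert ct.column_mean("HN", +2) == pytest.approx(0.04, abs=0.005)
        assert ct.column_mean("HA", -1) == pytest.approx(-0.03, abs=0.005)
        assert ct.column_mean("HA", +1) == pytest.approx(-0.02, abs=0.005)
        assert ct.column_mean("HA", +2) == pytest.approx(0.00, abs=0.005)
        # second-order (C2) means
        assert ct.column_mean("HN", -1, coefficient=2) == pytest.approx(-0.08, abs=0.005)

    def test_unknown_neighbor(self, db):
        with pytest.raises(hp.NotFoundError):
            db.correction_table.get("Xaa", "HN", -1)

    def test_offsets_without_data_are_silently_zero(self, db):
        assert db.correction_table.get("Ala", "HB_ALA", +1) == (0.0, 0.0)
        assert db.correction_table.get("Ala", "HN", -2) == (0.0, 0.0)


class TestDerive:
    def test_self_difference_is_zero(self):
        rec = derive_correction((0.52, -0.19), (0.52, -0.19),
                                neighbor="Gly", offset=-1, atom="HN")
        assert (rec.c1, rec.c2) == (0.0, 0.0)

    def test_elementwise_subtraction(self):
        rec = derive_correction((0.70, -0.30), (0.52, -0.19),
                                neighbor="Leu", offset=-1, atom="HN")
        assert rec.c1 == pytest.approx(0.18)
        assert rec.c2 == pytest.approx(-0.11)

    def test_reporter_mismatch_rejected(self, db):
        ala = db.lookup("Ala", "QB")
        val = db.lookup("Val", "HB")
        with pytest.raises(hp.UsageError):
            derive_correction(ala, val, neighbor="Leu", offset=-1, atom="HN")

    def test_closure_derive_then_apply_reconstructs_reporters(self):
        """Differencing per-peptide reporters and re-applying the table to
        the same tetrapeptide context must reproduce the reporter
        coefficients exactly (the construction is its own inverse)."""
        rng = np.random.default_rng(42)
        base = {"HN": (0.52, -0.19), "HA": (-0.02, 0.05)}
        variant_b = {}   # (y, atom) -> reporter coefficients in Ac-GGyA-NH2
        records = []
        for y in AA1_TO_3:
            for atom in ("HN", "HA"):
                bv = tuple(np.round(
                    np.asarray(base[atom]) + rng.normal(0, 0.1, 2), 4)) \
                    if y != "G" else base[atom]
                variant_b[(y, atom)] = bv
                records.append(derive_correction(
                    bv, base[atom], neighbor=y, offset=-1, atom=atom))
                # +1/+2 reporters: zero perturbation keeps the test focused
                for off in (+1, +2):
                    records.append(CorrectionRecord(
                        neighbor=hp.refdata.normalize_residue(y),
                        offset=off, atom=atom, c1=0.0, c2=0.0))
        table = CorrectionTable(records)
        for y in AA1_TO_3:
            for atom in ("HN", "HA"):
                ctx = SequenceContext(sequence=f"GG{y}A", index=3,
                                      n_term_cap="acetyl", c_term_cap="amide")
                cc = corrected_coefficients(_FakeDb(table), "Ala", atom, ctx,
                                            base=base[atom])
                assert (cc.b1, cc.b2) == pytest.approx(variant_b[(y, atom)])


class _FakeDb:
    def __init__(self, table):
        self.correction_table = table


class TestApply:
    def test_all_gly_context_unchanged(self, db):
        ctx = SequenceContext(sequence="GGAG", index=2)
        cc = corrected_coefficients(db, "Ala", "QB", ctx)
        rec = db.lookup("Ala", "QB")
        assert (cc.b1, cc.b2) == (rec.b1, rec.b2)
        assert cc.corrected

    def test_hn_sum_leu_asp_trp(self, db):
        # u=Leu (-1), y=Asp (+1), z=Trp (+2): 0.18 + 0.21 + 0.09
        ctx = SequenceContext(sequence="LADW", index=1)
        c1, c2 = neighbor_correction(db.correction_table, "HN", ctx)
        assert c1 == pytest.approx(0.48)

    def test_corrections_additive_and_offsetwise(self, db):
        ct = db.correction_table
        ctx = SequenceContext(sequence="LADW", index=1)
        total = neighbor_correction(ct, "HN", ctx)
        parts = [ct.get("Leu", "HN", -1), ct.get("Asp", "HN", 1),
                 ct.get("Trp", "HN", 2)]
        assert total[0] == pytest.approx(sum(p[0] for p in parts))
        assert total[1] == pytest.approx(sum(p[1] for p in parts))

    def test_chain_ends_contribute_zero(self, db):
        ctx = SequenceContext(sequence="AL", index=1)  # no +1/+2 neighbors
        c1, c2 = neighbor_correction(db.correction_table, "HN", ctx)
        assert c1 == pytest.approx(db.correction_table.get("Ala", "HN", -1)[0])

    def test_pro_target_has_no_amide_proton(self, db):
        ctx = SequenceContext(sequence="GPG", index=1)
        with pytest.raises(hp.NotFoundError):
            corrected_coefficients(db, "Pro", "HN", ctx, base=(0.5, -0.2))

    def test_uncovered_atom_returns_base_with_warning(self, db):
        ctx = SequenceContext(sequence="GVG", index=1)
        with pytest.warns(UserWarning, match="no neighbor-correction"):
            cc = corrected_coefficients(db, "Val", "HB", ctx)
        rec = db.lookup("Val", "HB")
        assert (cc.b1, cc.b2) == (rec.b1, rec.b2)
        assert not cc.corrected


class TestPredict:
    def test_gly_context_at_p0_returns_delta0(self, db):
        shifts, corrected = predict_random_coil_curve(
            db, "GGAG", 2, "QB", [0.1])
        assert shifts[0] == pytest.approx(db.lookup("Ala", "QB").delta0)
        assert corrected

    def test_ala_in_gly_context_matches_uncorrected_polynomial(self, db):
        rec = db.lookup("Ala", "QB")
        fit = PolynomialFit(delta0=rec.delta0, b1=rec.b1, b2=rec.b2)
        shifts, _ = predict_random_coil_curve(db, "GGAG", 2, "QB", [200.0])
        assert shifts[0] == pytest.approx(evaluate_shift(fit, 200.0), abs=1e-12)

    def test_his_without_ph_is_ambiguous(self, db):
        with pytest.raises(hp.AmbiguityError):
            predict_random_coil_curve(db, "GHG", 1, "HB2", [0.1, 100.0])

    def test_empty_pressures_rejected(self, db):
        with pytest.raises(hp.UsageError):
            predict_random_coil_curve(db, "GGAG", 2, "QB", [])

    def test_uncovered_atom_flag_false(self, db):
        shifts, corrected = predict_random_coil_curve(
            db, "GVG", 1, "HB", [0.1, 100.0])
        assert not corrected
        assert shifts[0] == pytest.approx(db.lookup("Val", "HB").delta0)
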