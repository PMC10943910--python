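"""Physicochemical descriptors: formula, mass, charge, pI, GRAVY, moment."""

import math

import numpy as np
import pytest

from conftest import random_peptides
from acpmine import _tables
from acpmine.properties import (ATOMIC_AVERAGE_MASS, ElementalFormula,
                                average_mass, elemental_formula, gravy,
                                hydrophobic_moment, isoelectric_point,
                                net_charge_hh, net_charge_integer,
                                property_report)


class TestElementalFormula:
    def test_free_glycine(self):
        assert elemental_formula("G") == ElementalFormula(C=2, H=5, N=1, O=2, S=0)

    def test_amalgam_printed_formula(self, amalgam):
        f = elemental_formula(amalgam)
        assert (f.C, f.H, f.N, f.O, f.S) == (197, 312, 52, 49, 0)
        assert str(f) == "C197H312N52O49"

    def test_condensation_identity(self, rng):
        for a, b in zip(random_peptides(rng, 10), random_peptides(rng, 10)):
            fa, fb, fab = elemental_formula(a), elemental_formula(b), elemental_formula(a + b)
            assert (fab.C, fab.H, fab.N, fab.O, fab.S) == (
                fa.C + fb.C, fa.H + fb.H - 2, fa.N + fb.N, fa.O + fb.O - 1, fa.S + fb.S)

    def test_rejects_invalid(self):
        with pytest.raises(Exception):
            elemental_formula("")
        with pytest.raises(Exception):
            elemental_formula("ABZ")


class TestMass:
    def test_glycine(self):
        assert average_mass("G") == pytest.approx(75.07, abs=0.01)

    def test_amalgam_printed_mass(self, amalgam):
        assert average_mass(amalgam) == pytest.approx(4192.92, abs=0.05)

    def test_additivity(self, rng):
        for a, b in zip(random_peptides(rng, 10), random_peptides(rng, 10)):
            assert average_mass(a + b) == pytest.approx(
                average_mass(a) + average_mass(b) - 18.01528, abs=1e-9)

    def test_formula_mass_cross_consistency(self, rng):
        """Atomic average masses applied to the formula track the mass table."""
        for pep in random_peptides(rng, 20):
            f = elemental_formula(pep)
            from_atoms = sum(getattr(f, el) * m for el, m in ATOMIC_AVERAGE_MASS.items())
            assert from_atoms == pytest.approx(average_mass(pep), abs=0.05)

    def test_monoisotopic_below_average(self, amalgam):
        assert average_mass(amalgam, "monoisotopic") < average_mass(amalgam)


class TestCharge:
    def test_amalgam_plus_five(self, amalgam):
        assert net_charge_integer(amalgam) == 5

    @pytest.mark.parametrize("pep,charge", [("KRDE", 0), ("HHH", 0), ("KKK", 3), ("EED", -3)])
    def test_counting_mode(self, pep, charge):
        assert net_charge_integer(pep) == charge

    def test_hh_monotone_in_pH(self, amalgam):
        grid = [net_charge_hh(amalgam, ph) for ph in np.linspace(0, 14, 30)]
        assert all(a > b for a, b in zip(grid, grid[1:]))

    def test_hh_acid_limit(self, amalgam):
        # 5 K + 3 R + N-terminus fully protonated at pH 0; no H in the sequence
        assert net_charge_hh(amalgam, 0.0) == pytest.approx(9.0, abs=0.02)

    def test_hh_matches_direct_sum_oracle(self, amalgam):
        pkas = _tables.load_pka_set("emboss")
        expected = 0.0
        for g in [aa for aa in amalgam if aa in "DECYHKR"] + ["nterm", "cterm"]:
            pka, kind = pkas[g]
            if kind == "basic":
                expected += 1 / (1 + 10 ** (7.0 - pka))
            else:
                expected -= 1 / (1 + 10 ** (pka - 7.0))
        assert net_charge_hh(amalgam, 7.0) == pytest.approx(expected, abs=1e-9)

    def test_counting_vs_hh_agree_without_hcy(self, rng):
        peps = [p.replace("H", "A").replace("C", "A").replace("Y", "A")
                for p in random_peptides(rng, 15)]
        for pep in peps:
            assert abs(net_charge_integer(pep) - net_charge_hh(pep, 7.0)) <= 1.0

    def test_hh_rejects_out_of_range_pH(self):
        with pytest.raises(ValueError):
            net_charge_hh("KK", 15.0)


class TestIsoelectricPoint:
    def test_glycine_midpoint(self):
        pkas = _tables.load_pka_set("emboss")
        mid = (pkas["nterm"][0] + pkas["cterm"][0]) / 2
        assert isoelectric_point("G") == pytest.approx(mid, abs=1e-3)

    def test_basic_above_acidic(self):
        assert isoelectric_point("KK") > isoelectric_point("EE")

    def test_amalgam_pI_basic(self, amalgam):
        pI = isoelectric_point(amalgam)
        assert pI > 7.0
        assert abs(net_charge_hh(amalgam, pI)) < 1e-3

    def test_no_ionizable_groups_errors(self):
        with pytest.raises(ValueError):
            isoelectric_point("AAA", include_termini=False)


class TestHydrophobicity:
    def test_homopolymer_gravy(self):
        scale = _tables.load_scale("kyte_doolittle")
        assert gravy("IIII") == pytest.approx(scale["I"], abs=1e-12)

    def test_gravy_permutation_invariant(self, amalgam):
        assert gravy(amalgam) == pytest.approx(gravy(amalgam[::-1]), abs=1e-12)

    def test_gravy_matches_mean_oracle(self, amalgam):
        scale = _tables.load_scale("kyte_doolittle")
        assert gravy(amalgam) == pytest.approx(
            sum(scale[a] for a in amalgam) / len(amalgam), abs=1e-12)

    def test_single_residue_moment(self):
        scale = _tables.load_scale("eisenberg")
        assert hydrophobic_moment("R") == pytest.approx(abs(scale["R"]), abs=1e-12)

    def test_homopolymer_18mer_cancels(self):
        # 18 residues x 100 deg = 5 full turns: vectors cancel exactly
        assert hydrophobic_moment("A" * 18) == pytest.approx(0.0, abs=1e-9)

    def test_moment_matches_trig_oracle(self, rng):
        scale = _tables.load_scale("eisenberg")
        for pep in random_peptides(rng, 20):
            sx = sum(scale[a] * math.cos(math.radians(100.0) * i) for i, a in enumerate(pep))
            sy = sum(scale[a] * math.sin(math.radians(100.0) * i) for i, a in enumerate(pep))
            assert hydrophobic_moment(pep) == pytest.approx(math.hypot(sx, sy), abs=1e-9)

    def test_moment_start_angle_invariant(self, rng):
        # re-indexing n -> n+k rotates every vector by the same phase,
        # leaving the magnitude unchanged
        scale = _tables.load_scale("eisenberg")
        for pep in random_peptides(rng, 10):
            for k in (1, 3, 7):
                sx = sum(scale[a] * math.cos(math.radians(100.0) * (i + k))
                         for i, a in enumerate(pep))
                sy = sum(scale[a] * math.sin(math.radians(100.0) * (i + k))
                         for i, a in enumerate(pep))
                assert math.hypot(sx, sy) == pytest.approx(
                    hydrophobic_moment(pep), abs=1e-9)


class TestPropertyReport:
    def test_amalgam_panel(self, amalgam):
        r = property_report(amalgam)
        assert r.length == 34
        assert r.formula == "C197H312N52O49"
        assert r.net_charge_integer == 5
        assert r.moment_per_residue == pytest.approx(r.hydrophobic_moment / 34, abs=1e-12)

    def test_glycine_panel(self):
        r = property_report("G")
        assert r.length == 1 and r.formula == "C2H5NO2"

    def test_deterministic(self, amalgam):
        assert property_report(amalgam) == property_report(amalgam)

    def test_serialization_round_trip(self, amalgam):
        text = property_report(amalgam).to_text()
        assert "net_charge_integer\t5" in text
        assert "formula\tC197H312N52O49" in text
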