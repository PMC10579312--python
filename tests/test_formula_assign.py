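"""Formula arithmetic, Senior validation, enumeration and assignment."""

import numpy as np
import pytest

from _oracles import oracle_enumerate
from somatlas import (
    AssignConfig,
    ElementBounds,
    MolecularFormula,
    apply_filters,
    assign_peaklist,
    enumerate_formulas,
    ion_mz_from_neutral,
    isotope_verify,
    monoisotopic_mass,
    neutral_mass_from_mz,
    senior_check,
    verify_table,
)
from somatlas.formula_assign import ION_TYPES, UnknownElementError
from somatlas.synth import PopulationConfig, generate_population, simulate_peaklist

F = MolecularFormula.parse


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("CH2", 14.0156500),
            ("H2O", 18.0105646),
            ("C2H5NO2", 75.0320284),  # glycine
            ("C6H12O6", 180.0633881),
        ],
    )
    def test_reference_masses(self, formula, expected):
        assert monoisotopic_mass(F(formula)) == pytest.approx(expected, abs=2e-7)

    def test_unknown_element_rejected(self):
        with pytest.raises(UnknownElementError):
            F("C2H5Br")

    def test_hill_order_roundtrip(self):
        for text in ("C8H11NNaO2", "C6H6", "CH4", "C12H26S4", "C5H8ClNO3"):
            assert F(text).hill == text
            assert F(F(text).hill) == F(text)


class TestIonArithmetic:
    def test_glycine_deprotonated(self):
        m = neutral_mass_from_mz(74.0247520, "[M-H]-")
        assert m == pytest.approx(75.0320284, abs=2e-7)

    def test_radical_cation_adds_electron_mass_only(self):
        assert neutral_mass_from_mz(300.0, "M+.") == pytest.approx(300.0005486, abs=1e-7)

    @pytest.mark.parametrize("ion", sorted(ION_TYPES))
    def test_neutral_ion_neutral_roundtrip(self, ion):
        for m in (75.0320284, 180.0633881, 499.123456):
            mz = ion_mz_from_neutral(m, ion)
            assert abs(neutral_mass_from_mz(mz, ion) - m) < 1e-9

    def test_nonpositive_neutral_rejected(self):
        with pytest.raises(ValueError):
            neutral_mass_from_mz(10.0, "[M+Cl]-")


class TestSeniorRules:
    @pytest.mark.parametrize(
        "formula,passes,dbe",
        [
            ("C6H6", True, 4.0),      # benzene
            ("CH3", False, 0.5),      # radical: half-integer DBE, odd H
            ("C2H8", False, -1.0),    # over-hydrogenated
            ("C2H5NO2", True, 1.0),   # glycine
            ("C12H26S4", True, 0.0),  # saturated polysulfane
            ("C6H5NaO2", True, 4.0),  # sodium phenolate-type salt
        ],
    )
    def test_reference_cases(self, formula, passes, dbe):
        got_pass, got_dbe = senior_check(F(formula))
        assert got_pass is passes or got_pass == passes
        assert got_dbe == pytest.approx(dbe)


class TestEnumeration:
    def test_glycine_unique_at_spec_bounds(self):
        bounds = ElementBounds(c=(1, 40), h=(0, 80), n=(0, 5), o=(0, 20), s=(0, 4))
        hits = enumerate_formulas(75.0320284, 0.2, bounds)
        assert [h.hill for h in hits] == ["C2H5NO2"]

    def test_matches_exhaustive_oracle(self, small_bounds):
        rng = np.random.default_rng(11)
        for mass in rng.uniform(80.0, 420.0, size=100):
            got = {f.counts for f in enumerate_formulas(mass, 5.0, small_bounds)}
            want = oracle_enumerate(mass, 5.0, small_bounds)
            assert got == want

    def test_tolerance_monotonicity(self, small_bounds):
        rng = np.random.default_rng(5)
        for mass in rng.uniform(100.0, 400.0, size=20):
            sets = [
                {f.counts for f in enumerate_formulas(mass, t, small_bounds)}
                for t in (0.0, 0.2, 2.0, 20.0)
            ]
            for smaller, larger in zip(sets, sets[1:]):
                assert smaller <= larger

    def test_planted_mass_always_recovered(self):
        pop = generate_population(PopulationConfig(n_formulas=200, seed=21))
        for f in pop:
            hits = enumerate_formulas(monoisotopic_mass(f), 0.2)
            assert f in hits

    def test_sorted_by_abs_error(self, small_bounds):
        hits = enumerate_formulas(250.1, 2000.0, small_bounds)
        errs = [
            abs((250.1 - monoisotopic_mass(f)) / monoisotopic_mass(f)) for f in hits
        ]
        assert errs == sorted(errs)


class TestApplyFilters:
    def test_hc_violation_flagged(self):
        res = apply_filters([F("CH30O2")])
        assert res.passed == []
        (formula, rules), = res.rejected
        assert "H/C" in rules

    def test_typical_cho_retained(self):
        res = apply_filters([F("C10H14O3")])
        assert [f.hill for f in res.passed] == ["C10H14O3"]

    def test_radical_flagged_senior(self):
        res = apply_filters([F("C6H5O")])
        assert "senior" in res.rejected[0][1]

    def test_idempotent(self):
        pop = [F("C10H14O3"), F("CH30O2"), F("C12H26S4"), F("C5H8N6S2")]
        once = apply_filters(pop)
        twice = apply_filters(once.passed)
        assert twice.passed == once.passed
        assert twice.rejected == []


class TestAssignment:
    def test_recovery_on_planted_population(self):
        """With 0.05 ppm jitter and a 0.2 ppm window, planted formulas are
        recovered as primary assignments essentially always."""
        pop = generate_population(
            PopulationConfig(n_formulas=200, seed=31, sulfur_series=True)
        )
        sim = simulate_peaklist(pop, ppm_sigma=0.05, noise_fraction=0.0, seed=32)
        table = assign_peaklist(sim.peaklist)
        prim = {a.peak.mz: a.formula for a in table.primaries}
        hits = sum(
            prim.get(p.mz) == f for p, f in zip(sim.peaklist.peaks, sim.truth)
        )
        assert hits / len(pop) >= 0.99

    def test_retained_assignments_internally_consistent(self):
        pop = generate_population(PopulationConfig(n_formulas=60, seed=41))
        sim = simulate_peaklist(pop, ppm_sigma=0.05, seed=42)
        table = assign_peaklist(sim.peaklist)
        assert table.assignments, "expected at least one assignment"
        for a in table.assignments:
            ok, d = senior_check(a.formula)
            assert ok and d == a.dbe
            theo = ion_mz_from_neutral(monoisotopic_mass(a.formula), a.ion_type)
            assert abs((a.peak.mz - theo) / theo * 1e6) <= 0.2
        for idx, count in table.ambiguity.items():
            cands = [a for a in table.assignments if a.peak_index == idx]
            assert len(cands) == count
            assert sum(a.is_primary for a in cands) == 1

    def test_noise_peaks_stay_unassigned(self):
        pop = generate_population(PopulationConfig(n_formulas=40, seed=51))
        sim = simulate_peaklist(pop, ppm_sigma=0.05, noise_fraction=0.3, seed=52)
        table = assign_peaklist(sim.peaklist)
        noise_idx = {i for i, f in enumerate(sim.truth) if f is None}
        assert sim.n_noise > 0
        assert not (noise_idx & set(table.ambiguity))

    def test_empty_peaklist(self, peaklist_factory):
        table = assign_peaklist(peaklist_factory([]))
        assert table.assignments == [] and table.ambiguity == {}


class TestIsotopeVerify:
    def _assigned(self, pl):
        table = assign_peaklist(pl)
        primaries = table.primaries
        assert primaries
        return table, primaries[0]

    def test_companion_at_expected_ratio_confirms(self, peaklist_factory):
        f = F("C20H30O5")  # n_C = 20 -> expected 13C companion at 21.4%
        mz = ion_mz_from_neutral(monoisotopic_mass(f), "[M-H]-")
        pl = peaklist_factory(
            [mz, mz + 1.0033548], intensity=[1e6, 0.214e6], snr=[200.0, 40.0]
        )
        _, a = self._assigned(pl)
        assert a.formula == f
        assert isotope_verify(a, pl).isotope_verified == "confirmed"

    def test_no_companion_low_evidence_is_unchecked(self, peaklist_factory):
        f = F("C5H10O5")
        mz = ion_mz_from_neutral(monoisotopic_mass(f), "[M-H]-")
        pl = peaklist_factory([mz], intensity=[1e4], snr=[8.0])
        _, a = self._assigned(pl)
        assert isotope_verify(a, pl).isotope_verified == "unchecked"

    def test_companion_far_off_ratio_contradicts(self, peaklist_factory):
        f = F("C20H30O5")
        mz = ion_mz_from_neutral(monoisotopic_mass(f), "[M-H]-")
        pl = peaklist_factory(
            [mz, mz + 1.0033548], intensity=[1e6, 2.14e6], snr=[200.0, 300.0]
        )
        _, a = self._assigned(pl)
        assert isotope_verify(a, pl).isotope_verified == "contradicted"

    def test_missing_companion_for_large_bright_ion_contradicts(self, peaklist_factory):
        f = F("C20H30O5")
        mz = ion_mz_from_neutral(monoisotopic_mass(f), "[M-H]-")
        pl = peaklist_factory([mz], intensity=[1e6], snr=[200.0])
        _, a = self._assigned(pl)
        assert isotope_verify(a, pl).isotope_verified == "contradicted"

    def test_verify_table_marks_all(self, peaklist_factory):
        pop = generate_population(PopulationConfig(n_formulas=30, seed=61))
        sim = simulate_peaklist(pop, ppm_sigma=0.0, seed=62)
        table = assign_peaklist(sim.peaklist)
        verify_table(table, sim.peaklist)
        assert all(
            a.isotope_verified in ("unchecked", "confirmed", "contradicted")
            for a in table.assignments
        )
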