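"""Peak picking, charge inference, deconvolution, composition, occupancy."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catpase_ms.native_ms import (
    SubunitEntry,
    SubunitMassTable,
    assign_composition,
    call_occupancy,
    deconvolute,
    explain_mass_shift,
    infer_charge,
    lipid_stoichiometry,
    pick_peaks,
)
from catpase_ms.spectra import MassSpectrum
from catpase_ms.synthetic_data import (
    GroundTruth,
    InstrumentModel,
    gen_native_spectrum,
    gen_occupancy_spectrum,
)


def single_species_spectrum(mass, zmin, zmax, resolution=1000.0, noise=0.0, seed=0):
    model = InstrumentModel(resolution=resolution, charge_range=(zmin, zmax),
                            noise_sd=noise)
    return gen_native_spectrum(
        GroundTruth(species=[("X", mass, 1.0)], seed=seed), model
    )


class TestPickPeaks:
    def test_single_gaussian_gives_one_peak_at_apex(self):
        mz = np.linspace(990, 1010, 2001)
        y = np.exp(-0.5 * ((mz - 1000.0) / 0.5) ** 2)
        peaks = pick_peaks(MassSpectrum(mz, y))
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(1000.0, abs=1e-6)

    def test_flat_zero_spectrum_gives_no_peaks(self):
        mz = np.linspace(100, 200, 500)
        assert pick_peaks(MassSpectrum(mz, np.zeros_like(mz))) == []

    def test_empty_spectrum_raises(self):
        with pytest.raises(ValueError):
            pick_peaks(MassSpectrum(np.array([]), np.array([])))

    def test_envelope_peak_count_matches_charge_states(self):
        sp = single_species_spectrum(400_000.0, 35, 45)
        assert len(pick_peaks(sp)) == 11


class TestInferCharge:
    def test_adjacent_pair_of_400kda_envelope(self):
        """(10001.007 - 1.007)/(10001.007 - 9757.10) = 41.0."""
        z1, ok, res = infer_charge(10001.007, 9757.10)
        assert z1 == 41 and ok and res < 0.01

    def test_every_adjacent_pair_of_exact_envelope(self):
        sp = single_species_spectrum(523_000.0, 40, 50)
        peaks = sorted(pick_peaks(sp), reverse=True)
        for i, ((m1, _), (m2, _)) in enumerate(zip(peaks, peaks[1:])):
            z1, ok, _ = infer_charge(m1, m2)
            assert ok and z1 == 41 + i

    def test_skipped_charge_state_is_flagged(self):
        spacing = 10001.007 - 9757.105
        z1, ok, res = infer_charge(10001.007, 10001.007 - 2 * spacing)
        assert not ok and res > 0.2

    def test_nonpositive_spacing_raises(self):
        with pytest.raises(ValueError):
            infer_charge(1000.0, 1000.0)


class TestDeconvolute:
    def test_single_species_round_trip(self):
        sp = single_species_spectrum(400_000.0, 35, 55)
        series = deconvolute(sp)
        assert len(series) == 1
        assert series[0].mass == pytest.approx(400_000.0, abs=4.0)
        assert series[0].charges == list(range(35, 56))

    def test_mixture_mass_difference(self):
        """523 + 400 kDa mixture deconvolves to a 123 kDa difference."""
        model = InstrumentModel(resolution=1000, charge_range=(35, 55))
        sp = gen_native_spectrum(
            GroundTruth(species=[("big", 523_000.0, 1.0), ("F1", 400_000.0, 0.8)]),
            model,
        )
        series = deconvolute(sp)
        assert len(series) == 2
        diff = abs(series[0].mass - series[1].mass)
        assert diff == pytest.approx(123_000.0, rel=1e-3)

    def test_too_few_peaks_raises(self):
        mz = np.linspace(990, 1010, 2001)
        y = np.exp(-0.5 * ((mz - 1000.0) / 0.5) ** 2)
        with pytest.raises(ValueError):
            deconvolute(MassSpectrum(mz, y))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        mass=st.floats(10_000.0, 1_000_000.0),
        zmin=st.integers(5, 55),
    )
    def test_mass_recovery_below_1e4_relative(self, mass, zmin):
        """Zero-noise recovery across 10 kDa - 1 MDa, charges 5-60."""
        sp = single_species_spectrum(mass, zmin, zmin + 5, resolution=2000.0)
        series = deconvolute(sp)
        assert abs(series[0].mass - mass) / mass < 1e-4

    def test_intensity_conservation(self):
        model = InstrumentModel(resolution=1000, charge_range=(35, 55))
        sp = gen_native_spectrum(
            GroundTruth(species=[("big", 523_000.0, 1.0), ("F1", 400_000.0, 0.8)]),
            model,
        )
        picked = pick_peaks(sp)
        series = deconvolute(sp)
        assert sum(s.abundance for s in series) <= sum(i for _, i in picked) + 1e-9


TOY_TABLE = SubunitMassTable(
    entries=[
        SubunitEntry("X", 10_000.0, 0, 3),
        SubunitEntry("Y", 4_000.0, 0, 2),
        SubunitEntry("Z", 1_500.0, 0, 2),
    ]
)


def brute_force_compositions(target, table, tol_da, lipid_bounds=(0, 0),
                             nucleotide_bounds=(0, 0)):
    items = [(e.name, e.mass, e.min_copies, e.max_copies) for e in table.entries]
    items.append(("lipid", table.lipid_mass, *lipid_bounds))
    items.append(("nucleotide", table.nucleotide_mass, *nucleotide_bounds))
    found = set()
    for counts in itertools.product(
        *[range(lo, hi + 1) for _, _, lo, hi in items]
    ):
        mass = sum(c * m for c, (_, m, _, _) in zip(counts, items))
        if abs(mass - target) <= tol_da:
            found.add(
                tuple(
                    sorted((n, c) for c, (n, _, _, _) in zip(counts, items) if c > 0)
                )
            )
    return found


def as_key_set(assignments):
    return {
        tuple(
            sorted(
                list(a.composition.items())
                + [
                    (n, c)
                    for n, c in (("lipid", a.lipids), ("nucleotide", a.nucleotides))
                    if c > 0
                ]
            )
        )
        for a in assignments
    }


class TestAssignComposition:
    def test_toy_table_unique_assignment(self):
        """35,500 Da decomposes uniquely as X3 Y1 Z1 at 10 Da tolerance."""
        res = assign_composition(35_500.0, TOY_TABLE, tol_da=10.0)
        assert len(res) == 1
        assert res[0].composition == {"X": 3, "Y": 1, "Z": 1}
        assert res[0].error_da == pytest.approx(0.0, abs=1e-9)

    def test_singleton_mass(self):
        res = assign_composition(4_000.0, TOY_TABLE, tol_da=1.0)
        assert res[0].composition == {"Y": 1} and res[0].error_da == 0.0

    def test_zero_target_gives_empty_composition(self):
        res = assign_composition(0.0, TOY_TABLE, tol_da=1.0)
        assert len(res) == 1 and res[0].total_copies == 0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            assign_composition(1000.0, SubunitMassTable(entries=[]), tol_da=1.0)

    def test_constraint_rules_filter(self):
        """A 'IV only with the ring' style rule removes candidates."""
        rule = lambda comp: comp.get("Z", 0) == 0 or comp.get("X", 0) > 0
        res = assign_composition(1_500.0, TOY_TABLE, tol_da=1.0, constraints=[rule])
        assert all(r.composition.get("Z", 0) == 0 or r.composition.get("X", 0) > 0
                   for r in res)
        assert not res  # the only 1500 Da candidate was Z1, X0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_oracle_equivalence_with_brute_force(self, data):
        """The pruned search finds exactly the brute-force composition set."""
        n = data.draw(st.integers(1, 4))
        entries = []
        for i in range(n):
            mass = data.draw(st.floats(500.0, 60_000.0))
            hi = data.draw(st.integers(1, 8)) if i else data.draw(st.integers(1, 14))
            entries.append(SubunitEntry(f"s{i}", mass, 0, hi))
        table = SubunitMassTable(entries=entries)
        target = data.draw(st.floats(0.0, 300_000.0))
        tol = data.draw(st.floats(1.0, 5_000.0))
        got = as_key_set(assign_composition(target, table, tol_da=tol))
        assert got == brute_force_compositions(target, table, tol)

    def test_tightening_tolerance_never_adds(self):
        wide = as_key_set(assign_composition(35_500.0, TOY_TABLE, tol_da=2000.0))
        narrow = as_key_set(assign_composition(35_500.0, TOY_TABLE, tol_da=100.0))
        assert narrow <= wide

    def test_ranked_by_mass_error(self):
        res = assign_composition(35_450.0, TOY_TABLE, tol_da=2000.0)
        errors = [abs(r.error_da) for r in res]
        assert errors == sorted(errors)
        assert [r.rank for r in res] == list(range(1, len(res) + 1))


class TestExplainMassShift:
    def test_met_loss_plus_acetylation(self):
        """-89.03 Da is explained by Met loss (-131.040) + acetyl (+42.011)."""
        combos = explain_mass_shift(-89.03, tolerance=0.05)
        assert combos[0][0] == {"Met-loss": 1, "N-acetylation": 1}

    def test_zero_shift_is_unmodified(self):
        combos = explain_mass_shift(0.0, tolerance=0.05)
        assert combos[0][0] == {}

    def test_double_oxidation(self):
        combos = explain_mass_shift(31.99, tolerance=0.05)
        assert combos[0][0] == {"oxidation": 2}

    def test_unexplainable_shift_gives_empty_list(self):
        assert explain_mass_shift(500.0, tolerance=0.01) == []


class TestLipidStoichiometry:
    def test_one_to_one_plug(self):
        per, nearest, resid = lipid_stoichiometry(10_500.0, 14, 750.0)
        assert per == pytest.approx(1.0) and nearest == 1 and resid == pytest.approx(0)

    def test_doubling(self):
        assert lipid_stoichiometry(21_000.0, 14, 750.0)[0] == pytest.approx(2.0)

    def test_zero_plug(self):
        assert lipid_stoichiometry(0.0, 14, 750.0)[0] == 0.0

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            lipid_stoichiometry(10_500.0, 0, 750.0)


class TestCallOccupancy:
    def test_exact_arithmetic(self):
        prof = call_occupancy(
            [(400_000.0, 1.0), (400_507.2, 2.0), (401_014.4, 4.0)], 507.2
        )
        assert [k for k, _ in prof.occupancies] == [0, 1, 2]
        assert prof.max_occupancy == 2
        assert prof.ratio == "1:2:4"
        assert sum(a for _, a in prof.occupancies) == pytest.approx(1.0)

    def test_single_species_has_zero_occupancy(self):
        prof = call_occupancy([(400_000.0, 1.0)], 507.2)
        assert prof.max_occupancy == 0

    def test_misfit_species_reported_unassigned(self):
        prof = call_occupancy(
            [(400_000.0, 1.0), (400_250.0, 1.0)], 507.2, tolerance=100.0
        )
        assert prof.unassigned and prof.unassigned[0][0] == 400_250.0

    def test_apo_override_anchors_base(self):
        """With no apo population left, the override recovers true counts."""
        prof = call_occupancy(
            [(401_014.4, 1.0), (401_521.6, 2.0)], 507.2, apo_mass=400_000.0
        )
        assert [k for k, _ in prof.occupancies] == [2, 3]
        assert prof.max_occupancy == 3

    def test_round_trip_from_spectrum(self):
        """Deconvolving a dephosphorylated-prep spectrum recovers 1:2:4:5."""
        model = InstrumentModel(resolution=5000, charge_range=(35, 55))
        sp = gen_occupancy_spectrum(400_000.0, 507.2, [1, 2, 4, 5], model)
        series = deconvolute(sp)
        prof = call_occupancy([(s.mass, s.abundance) for s in series], 507.2)
        assert prof.max_occupancy == 3
        assert prof.ratio == "1:2:4:5"
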