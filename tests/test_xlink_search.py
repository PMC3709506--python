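"""Digestion, candidate enumeration, scoring, isotope pairing, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from catpase_ms.constants import BS3_ISOTOPE_SHIFT, PROTON_MONO
from catpase_ms.spectra import MassSpectrum
from catpase_ms.synthetic_data import GroundTruth, gen_protein_sequences, gen_xl_run
from catpase_ms.xlink_search import (
    BS3_D0_D4,
    CrossLinkCandidate,
    Peptide,
    compute_fdr,
    detect_isotope_pair,
    digest,
    enumerate_candidates,
    expand_variable_mods,
    match_and_score,
    peptide_mass,
    score_spectrum,
    theoretical_fragments,
    validate,
)


class TestDigest:
    def test_cleavage_rule(self):
        """Cleave after K/R except before P: AKRPGKC -> AK, RPGK, C."""
        peps = digest("AKRPGKC", max_missed=0)
        assert [p.sequence for p in peps] == ["AK", "RPGK", "C"]
        assert [(p.start, p.end) for p in peps] == [(1, 2), (3, 6), (7, 7)]

    def test_one_missed_cleavage(self):
        peps = digest("AKRPGKC", max_missed=1)
        assert {p.sequence for p in peps if p.missed_cleavages == 1} == {
            "AKRPGK",
            "RPGKC",
        }

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACDKGRPSKR", min_size=1, max_size=40))
    def test_zero_missed_peptides_partition_sequence(self, seq):
        peps = [p for p in digest(seq, max_missed=2) if p.missed_cleavages == 0]
        assert "".join(p.sequence for p in peps) == seq

    def test_unknown_residue_raises(self):
        with pytest.raises(ValueError, match="unknown residue"):
            digest("AKBX")

    def test_mass_agrees_with_pyteomics(self):
        """Independent cross-check of the residue-sum mass computation."""
        for seq in ("PEPTIDE", "AKRPGKC", "MWCNQ"):
            assert peptide_mass(seq) == pytest.approx(
                pmass.calculate_mass(sequence=seq), abs=1e-6
            )

    def test_variable_mod_expansion_caps_at_three(self):
        (pep,) = [p for p in digest("MCMCMC") if p.missed_cleavages == 0]
        variants = expand_variable_mods([pep], max_mods=3)
        assert max(len(v.mods) for v in variants) == 3
        deltas = {round(v.mass - pep.mass, 3) for v in variants}
        assert 0.0 in deltas and round(57.02146, 3) in deltas


def make_pep(protein, seq, start, mass):
    return Peptide(protein, seq, start, start + len(seq) - 1, 1, mass)


class TestEnumerate:
    def test_precursor_mass_is_additive(self):
        """1000 + 800 + 138.0681 (d0 bridge) = 1938.068 Da."""
        p1 = make_pep("A", "GKG", 1, 1000.0)
        p2 = make_pep("B", "AKA", 1, 800.0)
        cands = enumerate_candidates({"A": [p1], "B": [p2]})
        d0 = [c for c in cands if c.isotope == "d0"]
        d4 = [c for c in cands if c.isotope == "d4"]
        assert len(d0) == len(d4) == 1
        assert d0[0].mass == pytest.approx(1938.068, abs=0.001)
        assert d4[0].mass - d0[0].mass == pytest.approx(4.025, abs=0.001)

    def test_symmetric_in_protein_order(self):
        p1 = make_pep("A", "GKG", 1, 1000.0)
        p2 = make_pep("B", "AKA", 1, 800.0)
        a = enumerate_candidates({"A": [p1], "B": [p2]})
        b = enumerate_candidates({"B": [p2], "A": [p1]})
        assert [(c.key, c.isotope, c.mass) for c in a] == [
            (c.key, c.isotope, c.mass) for c in b
        ]

    def test_c_terminal_lysine_not_linkable(self):
        """The linked K must be a missed-cleavage (internal) site."""
        pep = make_pep("A", "GGK", 1, 500.0)
        assert enumerate_candidates({"A": [pep, make_pep("A", "GKG", 5, 500.0)]}) == []


def complete_candidate():
    p1 = Peptide("A", "GKGR", 1, 4, 1, peptide_mass("GKGR"))
    p2 = Peptide("B", "AAKAR", 1, 5, 1, peptide_mass("AAKAR"))
    return CrossLinkCandidate(
        p1, p2, ("A", 2), ("B", 3), "d0", p1.mass + p2.mass + BS3_D0_D4.mass_d0
    )


class TestScoring:
    def test_complete_fragment_match_scores_one(self):
        cand = complete_candidate()
        frag_mz = sorted(mz for _, mz in theoretical_fragments(cand))
        sp = MassSpectrum(np.array(frag_mz), np.full(len(frag_mz), 50.0))
        score, nm, nt = score_spectrum(cand, sp)
        assert score == pytest.approx(1.0) and nm == nt

    def test_empty_spectrum_scores_zero(self):
        cand = complete_candidate()
        sp = MassSpectrum(np.array([]), np.array([]))
        assert score_spectrum(cand, sp)[0] == 0.0

    def test_crosslinked_fragments_carry_partner_mass(self):
        cand = complete_candidate()
        frags = dict(theoretical_fragments(cand))
        # A-peptide y3 covers residues KGR including the linked K
        xl_add = cand.pep2.mass + BS3_D0_D4.mass_d0
        plain_y3 = peptide_mass("KGR") + PROTON_MONO
        assert frags["Ay3"] == pytest.approx(plain_y3 + xl_add, abs=1e-6)
        # Ab1 covers only G, no cross-link
        assert frags["Ab1"] == pytest.approx(
            peptide_mass("G") - 18.0105646863 + PROTON_MONO, abs=1e-6
        )

    def test_precursor_tolerance_rejects_at_10ppm(self):
        """An observation 10.3 ppm away fails the 10 ppm filter."""

        class F:
            feature_id = "f1"
            z = 1
            rt = 0.0
            intensity = 1.0
            mz = 1938.088 + PROTON_MONO

        cand = complete_candidate()
        cand = CrossLinkCandidate(
            cand.pep1, cand.pep2, cand.link1, cand.link2, "d0", 1938.068
        )
        sp = MassSpectrum(np.array([200.0]), np.array([1.0]))
        hits = match_and_score([cand], [F()], {"f1": sp}, precursor_tol_ppm=10.0)
        assert hits == []
        hits = match_and_score([cand], [F()], {"f1": sp}, precursor_tol_ppm=11.0)
        assert len(hits) == 1


class TestIsotopePair:
    def test_pair_found_with_unit_ratio(self, small_sequences):
        truth = GroundTruth(links=[("alpha", 12, "beta", 24, 1.0)], seed=5)
        run = gen_xl_run(small_sequences, truth, charge=2)
        m = run.manifest["links"][0]
        assert m["mz_d4"] - m["mz_d0"] == pytest.approx(2.012554, abs=1e-5)
        peps = {n: digest(s, 2, n) for n, s in small_sequences.items()}
        hits = match_and_score(
            enumerate_candidates(peps), run.features, run.ms2
        )
        d0_hits = [h for h in hits if h.candidate.isotope == "d0"]
        assert d0_hits
        found, ratio = detect_isotope_pair(d0_hits[0], run.features)
        assert found and ratio == pytest.approx(1.0, rel=1e-6)

    def test_decoy_has_no_partner(self, xl_run):
        decoy_feats = [f for f in xl_run.features if f.feature_id.startswith("D")]
        assert decoy_feats
        peps = {}  # pair detection needs only the feature, fake a d0 hit
        cand = complete_candidate()

        class H:
            candidate = cand
            feature = decoy_feats[0]

        found, ratio = detect_isotope_pair(H(), xl_run.features)
        assert not found and np.isnan(ratio)

    def test_spacing_scales_with_charge(self, small_sequences):
        for z, expected in ((1, 4.025107), (4, 1.006277)):
            truth = GroundTruth(links=[("alpha", 12, "beta", 24, 1.0)], seed=5)
            run = gen_xl_run(small_sequences, truth, charge=z)
            m = run.manifest["links"][0]
            assert m["mz_d4"] - m["mz_d0"] == pytest.approx(expected, abs=1e-5)


def run_pipeline(sequences, run, min_score=0.3, require_pair=True,
                 precursor_tol_ppm=10.0, fragment_tol=0.8):
    peps = {n: digest(s, 2, n) for n, s in sequences.items()}
    cands = enumerate_candidates(peps)
    hits = match_and_score(cands, run.features, run.ms2,
                           precursor_tol_ppm=precursor_tol_ppm,
                           fragment_tol=fragment_tol)
    for h in hits:
        h.pair_found, h.pair_ratio = detect_isotope_pair(h, run.features)
    return validate(hits, min_score=min_score, require_pair=require_pair)


class TestValidate:
    def test_true_links_recovered_decoys_rejected(self, small_sequences, xl_truth,
                                                  xl_run):
        links, nc, nv = run_pipeline(small_sequences, xl_run)
        keys = {l.key for l in links}
        expected = {
            tuple(sorted(((p1, r1), (p2, r2))))
            for p1, r1, p2, r2, _ in xl_truth.links
        }
        assert keys == expected
        assert nv < nc  # decoy hits matched but were rejected

    def test_all_interprotein_for_cross_protein_truth(self, small_sequences,
                                                      xl_run):
        links, _, _ = run_pipeline(small_sequences, xl_run)
        assert all(l.is_interprotein for l in links)

    def test_ten_true_two_decoys_gives_ten_links(self):
        seqs = gen_protein_sequences(["p1", "p2"], length=160, seed=3)
        ks1 = [i + 1 for i, a in enumerate(seqs["p1"]) if a == "K"]
        ks2 = [i + 1 for i, a in enumerate(seqs["p2"]) if a == "K"]
        truth = GroundTruth(
            links=[("p1", a, "p2", b, 1.0) for a, b in zip(ks1[:10], ks2[:10])],
            seed=9,
        )
        run = gen_xl_run(seqs, truth, n_decoys=2)
        links, nc, nv = run_pipeline(seqs, run)
        assert len(links) == 10

    def test_widening_tolerances_never_removes_links(self, small_sequences, xl_run):
        narrow, _, _ = run_pipeline(small_sequences, xl_run,
                                    precursor_tol_ppm=5.0, fragment_tol=0.4)
        wide, _, _ = run_pipeline(small_sequences, xl_run,
                                  precursor_tol_ppm=20.0, fragment_tol=1.6)
        assert {l.key for l in narrow} <= {l.key for l in wide}

    def test_validated_mass_conservation(self, small_sequences, xl_run):
        links, _, _ = run_pipeline(small_sequences, xl_run)
        for link in links:
            for hit in link.hits:
                obs = hit.feature.z * (hit.feature.mz - PROTON_MONO)
                assert abs(obs - hit.candidate.mass) / hit.candidate.mass < 1e-5

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_recovery_across_seeds(self, small_sequences, seed):
        """Zero noise: every true link validated, every decoy rejected."""
        truth = GroundTruth(
            links=[("alpha", 24, "beta", 48, 1.0), ("beta", 12, "gamma", 36, 1.0)],
            seed=seed,
        )
        run = gen_xl_run(small_sequences, truth, n_decoys=1)
        links, nc, nv = run_pipeline(small_sequences, run)
        assert {l.key for l in links} == {
            (("alpha", 24), ("beta", 48)),
            (("beta", 12), ("gamma", 36)),
        }


class TestFdr:
    def test_all_validated_is_zero(self):
        assert compute_fdr(100, 100) == 0.0

    def test_none_validated_is_hundred(self):
        assert compute_fdr(10, 0) == 100.0

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            compute_fdr(0, 0)
        with pytest.raises(ValueError):
            compute_fdr(10, 11)
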