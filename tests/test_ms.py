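"""MS scoring: digestion, fragments, trimming, match scores, matching."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pmass

from ssfuse.core import Protein, bond
from ssfuse.ms import (
    AVG_H,
    MONO_H,
    MSConfig,
    DisulfidePair,
    Spectrum,
    TheoreticalFragmentSet,
    digest,
    enumerate_pairs,
    filter_by_precursor,
    global_topology,
    match_score_vs,
    p2_of,
    pp2_score,
    pp_score,
    read_mgf,
    theoretical_fragments,
    trim_search_space,
    write_mgf,
)

from conftest import brute_force_matching


class TestDigestionAndPairs:
    def test_toy_tryptic_pair(self):
        p = Protein(id="t", sequence="ACKRCK")
        pairs = enumerate_pairs(p, "trypsin", missed_cleavages=0)
        assert len(pairs) == 1
        (pair,) = pairs
        assert pair.bond == bond(2, 5)
        assert pair.peptide_a.sequence == "ACK"
        assert pair.peptide_b.sequence == "CK"

    def test_single_cysteine_no_pairs(self):
        p = Protein(id="t", sequence="ACKRGK")
        assert enumerate_pairs(p, "trypsin", 0) == []

    def test_pair_mass_loses_two_hydrogens(self):
        p = Protein(id="t", sequence="ACKRCK")
        (pair,) = enumerate_pairs(p, "trypsin", 0)
        expected = pmass.fast_mass("ACK") + pmass.fast_mass("CK") - 2 * MONO_H
        assert pair.mass == pytest.approx(expected, abs=1e-6)

    def test_intra_peptide_bond(self):
        p = Protein(id="t", sequence="ACGCAK")
        pairs = enumerate_pairs(p, "trypsin", 0)
        intra = [q for q in pairs if q.intra]
        assert len(intra) == 1
        assert intra[0].bond == bond(2, 4)
        assert intra[0].mass == pytest.approx(
            pmass.fast_mass("ACGCAK") - 2 * MONO_H, abs=1e-6
        )

    def test_peptide_locations_are_one_based(self):
        p = Protein(id="t", sequence="ACKRCK")
        peptides = digest(p, "trypsin", 0)
        assert [(pep.sequence, pep.start) for pep in peptides] == [
            ("ACK", 1), ("R", 4), ("CK", 5),
        ]


class TestTrimming:
    def test_documented_example(self):
        assert trim_search_space([100.0, 100.5, 101.0, 200.0], 0.01) == [100.0, 200.0]

    def test_tiny_epsilon_keeps_everything(self):
        masses = [100.0, 100.5, 101.0, 200.0]
        assert trim_search_space(masses, 1e-12) == masses

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        epsilon=st.floats(1e-6, 0.5, allow_nan=False),
    )
    def test_every_removed_mass_has_close_kept_representative(self, seed, epsilon):
        rng = np.random.default_rng(seed)
        masses = sorted(rng.uniform(100, 5000, size=40).tolist())
        kept = trim_search_space(masses, epsilon)
        kept_set = set(kept)
        for m in masses:
            if m in kept_set:
                continue
            assert any(m / (1 + epsilon) <= k <= m for k in kept), (m, epsilon)


class TestFragments:
    def test_all_twelve_ion_series_present(self):
        p = Protein(id="t", sequence="ACKRCK")
        (pair,) = enumerate_pairs(p, "trypsin", 0)
        theo = theoretical_fragments(pair)
        assert {f.ion_type for f in theo.fragments} == {
            "a", "a-H2O", "a-NH3", "b", "b-H2O", "b-NH3",
            "c", "x", "y", "y-H2O", "y-NH3", "z",
        }
        assert all(f.mz > 0 for f in theo.fragments)

    def test_cysteine_retaining_fragment_carries_partner(self):
        p = Protein(id="t", sequence="ACKRCK")
        (pair,) = enumerate_pairs(p, "trypsin", 0)
        theo = theoretical_fragments(pair)
        # y2 of ACK (site 1, suffix CK) retains C2: partner CK (-2H) attached
        linked_y2 = pmass.fast_mass("CK", ion_type="y", charge=1) + (
            pmass.fast_mass("CK") - 2 * MONO_H
        )
        assert any(
            f.ion_type == "y" and f.source == "a"
            and f.mz == pytest.approx(linked_y2, abs=1e-5)
            for f in theo.fragments
        )
        # b1 of ACK (prefix A) does not retain C2: plain backbone mass
        plain_b1 = pmass.fast_mass("A", ion_type="b", charge=1)
        assert any(
            f.ion_type == "b" and f.source == "a"
            and f.mz == pytest.approx(plain_b1, abs=1e-5)
            for f in theo.fragments
        )

    def test_precursor_filter(self):
        p = Protein(id="t", sequence="ACKRCKGGCKAACK")
        pairs = enumerate_pairs(p, "trypsin", 0)
        target = pairs[0].mass
        kept = filter_by_precursor(pairs, target, tolerance=0.5)
        assert pairs[0] in kept
        assert all(abs(q.mass - target) <= 0.5 for q in kept)


class TestScores:
    def make_theo(self, mzs):
        p = Protein(id="t", sequence="ACKRCK")
        (pair,) = enumerate_pairs(p, "trypsin", 0)
        from ssfuse.ms import Fragment

        return TheoreticalFragmentSet(
            pair=pair,
            fragments=[Fragment(ion_type="b", mz=m, source="a") for m in mzs],
        )

    def test_all_peaks_matched_gives_vs_100(self):
        theo = self.make_theo([100.0, 200.0, 300.0])
        spec = Spectrum(
            precursor_mass=500.0, precursor_charge=1,
            peaks=[(100.0, 50.0), (200.0, 80.0), (300.0, 30.0)],
        )
        rep = match_score_vs(spec, theo, tolerance=0.5)
        assert rep.vs_score == pytest.approx(100.0)
        assert rep.n_match == 3

    def test_intensity_weighted_fraction(self):
        theo = self.make_theo([100.0, 200.0])
        spec = Spectrum(
            precursor_mass=500.0, precursor_charge=1,
            peaks=[(100.0, 100.0), (200.0, 50.0), (900.0, 50.0)],
        )
        rep = match_score_vs(spec, theo, tolerance=0.5)
        assert rep.vs_score == pytest.approx(75.0)  # 150 of 200 total intensity

    def test_no_matches_gives_zero(self):
        theo = self.make_theo([100.0])
        spec = Spectrum(
            precursor_mass=500.0, precursor_charge=1, peaks=[(700.0, 10.0)]
        )
        assert match_score_vs(spec, theo, tolerance=0.5).vs_score == 0.0

    def test_intensity_floor_drops_weak_peaks(self):
        theo = self.make_theo([100.0])
        spec = Spectrum(
            precursor_mass=500.0, precursor_charge=1,
            peaks=[(100.0, 5.0), (700.0, 100.0)],  # match is below 10% floor
        )
        rep = match_score_vs(spec, theo, tolerance=0.5, intensity_floor=0.1)
        assert rep.vs_score == 0.0

    def test_empty_theoretical_set_rejected(self):
        spec = Spectrum(precursor_mass=1.0, precursor_charge=1, peaks=[(1.0, 1.0)])
        with pytest.raises(ValueError):
            match_score_vs(spec, self.make_theo([]), tolerance=0.5)

    @pytest.mark.parametrize(
        "n, n_match, p2, expected",
        [(10, 0, 0.01, 0.0), (5, 5, 0.01, 10.0)],
    )
    def test_pp_values(self, n, n_match, p2, expected):
        assert pp_score(n, n_match, p2) == pytest.approx(expected, abs=1e-6)

    def test_pp_monotone_in_match_count(self):
        vals = [pp_score(20, k, 0.05) for k in range(21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_p2_arithmetic(self):
        assert p2_of(10, 0.5, 1000.0) == pytest.approx(0.01)

    def test_p2_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            p2_of(0, 0.5, 1000.0)
        with pytest.raises(ValueError):
            p2_of(10, 0.5, 0.0)

    def test_p2_clamped_below_one(self):
        assert 0.0 < p2_of(10_000, 0.5, 10.0) < 1.0

    def test_pp2_median_abundance(self):
        assert pp2_score(50.0, 50.0, 10.0) == pytest.approx(-math.log10(0.5), abs=1e-6)

    def test_pp2_monotone_in_matched_abundance(self):
        vals = [pp2_score(x, 50.0, 10.0) for x in (0.0, 25.0, 50.0, 75.0, 100.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert pp2_score(-1e6, 50.0, 10.0) == pytest.approx(0.0, abs=1e-9)


class TestGlobalTopology:
    def test_rejects_greedy_trap(self):
        scores = {bond(1, 2): 0.9, bond(3, 4): 0.8, bond(2, 3): 0.95}
        topo = global_topology(scores)
        assert set(topo.bonds) == {bond(1, 2), bond(3, 4)}

    def test_single_edge(self):
        assert set(global_topology({bond(1, 2): 0.5}).bonds) == {bond(1, 2)}

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            global_topology({bond(1, 2): -0.1})

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n_cys=st.integers(2, 8))
    def test_matches_brute_force_optimum(self, seed, n_cys):
        rng = np.random.default_rng(seed)
        cys = list(range(1, n_cys + 1))
        edges = list(itertools.combinations(cys, 2))
        rng.shuffle(edges)
        chosen = edges[: min(len(edges), 10)]
        scores = {bond(a, b): float(rng.random()) for a, b in chosen}
        topo = global_topology(scores)
        achieved = sum(scores[b] for b in topo.bonds)
        assert achieved == pytest.approx(brute_force_matching(scores), abs=1e-9)

    def test_deterministic_across_runs(self):
        scores = {bond(1, 2): 0.5, bond(2, 3): 0.5, bond(3, 4): 0.5}
        assert global_topology(scores).bonds == global_topology(scores).bonds


class TestMGFRoundTrip:
    def test_round_trip(self, tmp_path):
        spec = Spectrum(
            precursor_mass=1500.0,
            precursor_charge=2,
            peaks=[(100.0, 10.0), (250.5, 55.0)],
            title="t1",
        )
        path = tmp_path / "s.mgf"
        write_mgf([spec], path)
        (back,) = read_mgf(path)
        assert back.precursor_mass == pytest.approx(1500.0, abs=1e-4)
        assert back.precursor_charge == 2
        assert back.peaks[0][0] == pytest.approx(100.0)
        assert back.peaks[1][1] == pytest.approx(55.0)
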