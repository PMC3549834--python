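"""The four combination rules against hand evaluations and an exhaustive
tuple-enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssfuse import fixtures
from ssfuse.combine import (
    DiscountWeights,
    TotalConflictError,
    bond_scores,
    combine,
    combine_campos,
    combine_dempster,
    combine_shafer,
    combine_yager,
    discount,
)
from ssfuse.core import bond
from ssfuse.hypothesis import FocalSet, MassFunction
from ssfuse.pipeline import fuse_evidence

from conftest import oracle_rule, random_mass_function

A = FocalSet({bond(1, 2)})
B = FocalSet({bond(3, 4)})

SMALL_BONDS = [bond(1, 2), bond(3, 4), bond(5, 6), bond(2, 3)]


@pytest.fixture
def conflicting_pair():
    m1 = MassFunction(entries={A: 0.6}, environment_mass=0.4)
    m2 = MassFunction(entries={B: 0.5}, environment_mass=0.5)
    return m1, m2


def example1_masses():
    ev = fixtures.example1_evidence()
    return [
        MassFunction.from_singleton_scores({e.bond: e.belief for e in ev[m]})
        for m in ("M1", "M2")
    ]


class TestDempster:
    def test_conflicting_sources_inflate_common_low_belief_bond(self):
        # two methods that disagree strongly but share one low-confidence
        # bond: the rule assigns it everything
        res = combine_dempster(example1_masses())
        scores = bond_scores(res)
        assert scores[bond(14, 31)] == pytest.approx(1.0)
        assert all(
            v == pytest.approx(0.0) for b, v in scores.items() if b != bond(14, 31)
        )
        assert res.conflict_weight > 0

    def test_identical_certain_sources(self):
        m = MassFunction(entries={A: 1.0})
        res = combine_dempster([m, m])
        assert res.fused.entries[A] == pytest.approx(1.0)
        assert res.conflict_mass == 0.0
        assert res.conflict_weight == 0.0

    def test_hand_evaluation(self, conflicting_pair):
        res = combine_dempster(list(conflicting_pair))
        assert res.conflict_mass == pytest.approx(0.30)
        assert res.fused.entries[A] == pytest.approx(0.6 * 0.5 / 0.7)
        assert res.fused.entries[B] == pytest.approx(0.2 / 0.7)
        assert res.fused.environment_mass == pytest.approx(0.2 / 0.7)

    def test_total_conflict_raises(self):
        m1 = MassFunction(entries={A: 1.0})
        m2 = MassFunction(entries={B: 1.0})
        with pytest.raises(TotalConflictError):
            combine_dempster([m1, m2])


class TestYager:
    def test_total_conflict_goes_to_environment(self):
        m1 = MassFunction(entries={A: 1.0})
        m2 = MassFunction(entries={B: 1.0})
        res = combine_yager([m1, m2])
        assert res.fused.environment_mass == pytest.approx(1.0)
        assert bond_scores(res) == {}

    def test_hand_evaluation(self, conflicting_pair):
        res = combine_yager(list(conflicting_pair))
        assert res.fused.entries[A] == pytest.approx(0.30)
        assert res.fused.entries[B] == pytest.approx(0.20)
        assert res.fused.environment_mass == pytest.approx(0.50)

    def test_case_study_suppresses_all_bonds(self):
        # MS and SVM report disjoint connectivities and CSP is vacuous:
        # without normalisation everything lands in the environment
        out = fuse_evidence(fixtures.table4_evidence(), rule="yager")
        assert all(v < 0.01 for v in out.scores.values())
        assert out.result.fused.environment_mass > 0.99


class TestCampos:
    def test_zero_conflict_equals_dempster(self):
        m1 = MassFunction(entries={A: 0.7}, environment_mass=0.3)
        m2 = MassFunction(entries={A: 0.4}, environment_mass=0.6)
        d = combine_dempster([m1, m2])
        c = combine_campos([m1, m2])
        assert c.conflict_mass == 0.0
        for focal in d.fused.entries:
            assert c.fused.entries[focal] == pytest.approx(d.fused.entries[focal])
        assert c.fused.environment_mass == pytest.approx(d.fused.environment_mass)

    def test_hand_evaluation_derates_by_conflict_weight(self, conflicting_pair):
        res = combine_campos(list(conflicting_pair))
        factor = 1.0 + math.log(1.0 / 0.7)
        assert res.fused.entries[A] == pytest.approx((0.3 / 0.7) / factor)
        # deficit is returned to the environment, masses still sum to 1
        total = sum(res.fused.entries.values()) + res.fused.environment_mass
        assert total == pytest.approx(1.0)

    def test_total_conflict_raises(self):
        m1 = MassFunction(entries={A: 1.0})
        m2 = MassFunction(entries={B: 1.0})
        with pytest.raises(TotalConflictError):
            combine_campos([m1, m2])


class TestShafer:
    def test_mean_of_identical_fully_reliable_sources(self):
        m = MassFunction(entries={A: 0.8}, environment_mass=0.2)
        res = combine_shafer([m, m], [1.0, 1.0])
        assert res.fused.entries[A] == pytest.approx(0.8)
        assert res.fused.environment_mass == pytest.approx(0.2)

    def test_unreliable_source_becomes_vacuous(self):
        m1 = MassFunction(entries={A: 0.8}, environment_mass=0.2)
        m2 = MassFunction(entries={B: 0.9}, environment_mass=0.1)
        res = combine_shafer([m1, m2], [1.0, 0.0])
        assert res.fused.entries[A] == pytest.approx(0.40)
        assert res.fused.entries.get(B, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert res.fused.environment_mass == pytest.approx(0.60)

    def test_discount_weights_objects_accepted(self):
        m = MassFunction(entries={A: 0.8}, environment_mass=0.2)
        res = combine_shafer(
            [m, m],
            [DiscountWeights("MS", 1.0), DiscountWeights("SVM", 0.5)],
        )
        assert res.fused.entries[A] == pytest.approx((0.8 + 0.4) / 2)

    def test_bad_alpha_rejected(self):
        m = MassFunction(entries={A: 1.0})
        with pytest.raises(ValueError):
            combine_shafer([m, m], [1.0, 1.5])

    def test_discounting_moves_mass_to_environment(self):
        m = MassFunction(entries={A: 0.6, B: 0.2}, environment_mass=0.2)
        d = discount(m, 0.5)
        assert d.entries[A] == pytest.approx(0.3)
        assert d.environment_mass == pytest.approx(0.5 + 0.1)


class TestBondScores:
    def test_containment_sum(self):
        m = MassFunction(
            entries={A: 0.4, FocalSet({bond(1, 2), bond(3, 4)}): 0.2},
            environment_mass=0.4,
        )
        from ssfuse.combine import CombinationResult

        res = CombinationResult(fused=m, conflict_mass=0.0, conflict_weight=0.0, rule="yager")
        scores = bond_scores(res)
        assert scores[bond(1, 2)] == pytest.approx(0.6)
        assert scores[bond(3, 4)] == pytest.approx(0.2)


class TestRuleProperties:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n_sources=st.integers(2, 3))
    def test_rules_match_exhaustive_oracle(self, seed, n_sources):
        rng = np.random.default_rng(seed)
        masses = [random_mass_function(rng, SMALL_BONDS) for _ in range(n_sources)]
        alphas = [float(rng.random()) for _ in range(n_sources)]
        for rule in ("dempster", "yager", "campos", "shafer"):
            try:
                res = combine(masses, rule, weights=alphas if rule == "shafer" else None)
            except TotalConflictError:
                continue
            entries, env, conflict = oracle_rule(
                masses, rule, alphas if rule == "shafer" else None
            )
            all_focals = set(res.fused.entries) | set(entries)
            for focal in all_focals:
                assert res.fused.entries.get(focal, 0.0) == pytest.approx(
                    entries.get(focal, 0.0), abs=1e-12
                ), rule
            assert res.fused.environment_mass == pytest.approx(env, abs=1e-12), rule

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_source_order_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        masses = [random_mass_function(rng, SMALL_BONDS) for _ in range(3)]
        alphas = [0.9, 0.6, 0.3]
        for rule in ("dempster", "yager", "campos", "shafer"):
            results = []
            for perm in itertools.permutations(range(3)):
                try:
                    res = combine(
                        [masses[i] for i in perm],
                        rule,
                        weights=[alphas[i] for i in perm] if rule == "shafer" else None,
                    )
                except TotalConflictError:
                    results.append(None)
                    continue
                results.append(res)
            ok = [r for r in results if r is not None]
            assert len(ok) in (0, 6)
            for r in ok[1:]:
                for focal, v in ok[0].fused.entries.items():
                    assert r.fused.entries.get(focal, 0.0) == pytest.approx(v, abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_mass_conservation_for_every_rule(self, seed):
        rng = np.random.default_rng(seed)
        masses = [random_mass_function(rng, SMALL_BONDS) for _ in range(3)]
        for rule in ("dempster", "yager", "campos", "shafer"):
            try:
                res = combine(
                    masses, rule, weights=[0.8, 0.5, 1.0] if rule == "shafer" else None
                )
            except TotalConflictError:
                continue
            total = sum(res.fused.entries.values()) + res.fused.environment_mass
            assert total == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_pairwise_dempster_equals_nary(self, seed):
        rng = np.random.default_rng(seed)
        masses = [random_mass_function(rng, SMALL_BONDS) for _ in range(3)]
        try:
            nary = combine_dempster(masses)
            step = combine_dempster([combine_dempster(masses[:2]).fused, masses[2]])
        except TotalConflictError:
            return
        for focal in set(nary.fused.entries) | set(step.fused.entries):
            assert step.fused.entries.get(focal, 0.0) == pytest.approx(
                nary.fused.entries.get(focal, 0.0), abs=1e-9
            )

    def test_zero_conflict_rules_coincide(self):
        # sources whose focal sets all intersect: no conflict anywhere
        m1 = MassFunction(entries={A: 0.5}, environment_mass=0.5)
        m2 = MassFunction(entries={A: 0.3}, environment_mass=0.7)
        d = combine_dempster([m1, m2])
        y = combine_yager([m1, m2])
        c = combine_campos([m1, m2])
        assert d.conflict_mass == 0.0
        for focal, v in d.fused.entries.items():
            assert y.fused.entries[focal] == pytest.approx(v)
            assert c.fused.entries[focal] == pytest.approx(v)
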