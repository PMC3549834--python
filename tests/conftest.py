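"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ssfuse.core import BondHypothesis, bond, is_consistent
from ssfuse.hypothesis import FocalSet, MassFunction

ENV = "ENV"  # oracle-side sentinel for the environment


@pytest.fixture
def rng():
    return np.random.default_rng(20130121)


def powerset_consistent_oracle(hypotheses, max_card):
    """Filter the full power set by the matching test (exhaustive)."""
    out = []
    for r in range(1, max_card + 1):
        for combo in itertools.combinations(hypotheses, r):
            if is_consistent(combo):
                out.append(frozenset(combo))
    return out


def _oracle_elements(mass: MassFunction):
    els = [(frozenset(f), m) for f, m in mass.entries.items()]
    if mass.environment_mass:
        els.append((ENV, mass.environment_mass))
    return els


def oracle_products(masses):
    """Exhaustive tuple enumeration of the joint focal products.

    Returns (dict intersection -> mass, conflict, environment product).
    Written independently of the library's enumeration (explicit tuple
    recursion over focal elements with an environment token).
    """
    accr, conflict, envp = {}, 0.0, 0.0
    element_lists = [_oracle_elements(m) for m in masses]

    def rec(i, current, product):
        nonlocal conflict, envp
        if i == len(element_lists):
            if current == ENV:
                envp += product
            elif len(current) == 0:
                conflict += product
            else:
                accr[current] = accr.get(current, 0.0) + product
            return
        for focal, m in element_lists[i]:
            if focal == ENV:
                nxt = current
            elif current == ENV:
                nxt = focal
            else:
                nxt = current & focal
            rec(i + 1, nxt, product * m)

    rec(0, ENV, 1.0)
    return accr, conflict, envp


def oracle_rule(masses, rule, alphas=None):
    """Independent evaluation of a combination rule via oracle_products."""
    import math

    if rule == "shafer":
        n = len(masses)
        entries, env = {}, 0.0
        for m, a in zip(masses, alphas):
            for focal, v in m.entries.items():
                entries[frozenset(focal)] = entries.get(frozenset(focal), 0.0) + a * v / n
            env += (1.0 - a + a * m.environment_mass) / n
        return entries, env, 0.0
    accr, conflict, envp = oracle_products(masses)
    if rule == "yager":
        return accr, envp + conflict, conflict
    denom = 1.0 - conflict
    entries = {f: v / denom for f, v in accr.items()}
    env = envp / denom
    if rule == "dempster":
        return entries, env, conflict
    if rule == "campos":
        factor = 1.0 + math.log(1.0 / denom)
        entries = {f: v / factor for f, v in entries.items()}
        env = env / factor
        env += 1.0 - sum(entries.values()) - env
        return entries, env, conflict
    raise ValueError(rule)


def brute_force_matching(bond_scores):
    """Optimal matching weight by exhaustive subset enumeration."""
    edges = sorted(bond_scores)
    best = 0.0
    for r in range(len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            if is_consistent(combo):
                best = max(best, sum(bond_scores[b] for b in combo))
    return best


def random_mass_function(rng, bonds, max_focal=4):
    """Random valid mass function over consistent subsets of ``bonds``."""
    candidates = powerset_consistent_oracle(bonds, 2)
    k = int(rng.integers(1, min(max_focal, len(candidates)) + 1))
    picks = rng.choice(len(candidates), size=k, replace=False)
    raw = rng.random(k + 1)
    raw /= raw.sum()
    entries = {candidates[int(i)]: float(w) for i, w in zip(picks, raw[:-1])}
    return MassFunction(entries=entries, environment_mass=float(raw[-1]))


@pytest.fixture
def small_bonds():
    return [bond(1, 2), bond(3, 4), bond(5, 6), bond(2, 3)]
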