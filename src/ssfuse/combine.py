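"""Evidence combination: Dempster, Yager, Campos and Shafer rules.

All product-based rules are applied in their n-ary simultaneous form: take
one focal element from each source (the environment counts as a focal
element), multiply the masses, and accrue the product to the intersection
of the tuple.  The environment acts as identity under intersection; two
focal sets whose plain set intersection is empty contribute *conflict*
mass.  The rules differ only in what happens to the conflict:

- Dempster: conflict is normalised out (divide by 1 - conflict); fails
  loudly on total conflict.
- Yager: conflict is added to the environment, enlarging ignorance.
- Campos: the Dempster orthogonal sum is de-rated by 1/(1 + log X), where
  log X = log(1/(1 - conflict)) is the weight of conflict, and the deficit
  goes to the environment.
- Shafer: no products at all — each source is discounted by a reliability
  weight alpha (masses scaled by alpha, the remainder joining that
  source's environment) and the discounted mass functions are averaged
  focal-set by focal-set.

The weight of conflict uses the natural logarithm; it is 0 when sources do
not conflict and diverges as conflict approaches totality.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .core import BondHypothesis
from .hypothesis import FocalSet, MassFunction

Rule = Literal["dempster", "yager", "campos", "shafer"]

#: sentinel for the environment in tuple enumeration
_ENV = None


class TotalConflictError(ValueError):
    """All joint evidence mass is conflicting; the rule's result is undefined."""


@dataclass
class CombinationResult:
    fused: MassFunction
    conflict_mass: float
    conflict_weight: float
    rule: Rule


@dataclass(frozen=True)
class DiscountWeights:
    """Per-source reliability factor alpha in [0, 1] (1 = fully reliable)."""

    method: str
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"discount weight must lie in [0, 1], got {self.alpha}")


def _elements(mass: MassFunction) -> list[tuple[FocalSet | None, float]]:
    els: list[tuple[FocalSet | None, float]] = [
        (focal, m) for focal, m in mass.entries.items() if m > 0.0
    ]
    if mass.environment_mass > 0.0:
        els.append((_ENV, mass.environment_mass))
    return els


def _joint_products(
    masses: Sequence[MassFunction],
) -> tuple[dict[FocalSet, float], float, float]:
    """Enumerate all focal-element tuples across the sources.

    Returns (accrued mass per non-empty intersection, conflict mass,
    environment product mass).
    """
    if len(masses) < 2:
        raise ValueError("combination needs at least two mass functions")
    accrued: dict[FocalSet, float] = {}
    conflict = 0.0
    env_product = 0.0
    for tup in itertools.product(*(_elements(m) for m in masses)):
        product = 1.0
        inter: FocalSet | None = _ENV
        for focal, m in tup:
            product *= m
            if focal is _ENV:
                continue
            inter = focal if inter is _ENV else inter & focal
        if inter is _ENV:
            env_product += product
        elif inter:
            accrued[inter] = accrued.get(inter, 0.0) + product
        else:
            conflict += product
    return accrued, conflict, env_product


def conflict_weight_of(conflict_mass: float) -> float:
    """Weight of conflict log(X), X = 1/(1 - conflict); natural log."""
    if conflict_mass >= 1.0:
        return math.inf
    return math.log(1.0 / (1.0 - conflict_mass))


def combine_dempster(masses: Sequence[MassFunction]) -> CombinationResult:
    """N-ary Dempster rule: conflict normalised out.

    Raises :class:`TotalConflictError` when the sources are totally
    conflicting (the normaliser is zero) — there is no silent fallback.
    """
    accrued, conflict, env_product = _joint_products(masses)
    # normalise by the surviving product mass (== 1 - conflict, but exact
    # under floating point so fused masses sum to 1)
    denom = sum(accrued.values()) + env_product
    if denom <= 0.0:
        raise TotalConflictError(
            "total conflict between sources; the Dempster rule is undefined"
        )
    fused = MassFunction(
        entries={focal: m / denom for focal, m in accrued.items()},
        environment_mass=env_product / denom,
    )
    return CombinationResult(
        fused=fused,
        conflict_mass=conflict,
        conflict_weight=conflict_weight_of(conflict),
        rule="dempster",
    )


def combine_yager(masses: Sequence[MassFunction]) -> CombinationResult:
    """N-ary Yager rule: conflicting mass enlarges the environment."""
    accrued, conflict, env_product = _joint_products(masses)
    fused = MassFunction(
        entries=dict(accrued), environment_mass=env_product + conflict
    )
    return CombinationResult(
        fused=fused,
        conflict_mass=conflict,
        conflict_weight=conflict_weight_of(conflict),
        rule="yager",
    )


def combine_campos(masses: Sequence[MassFunction]) -> CombinationResult:
    """Campos-Cavalcante rule: Dempster orthogonal sum de-rated by the
    weight of conflict, deficit assigned to the environment."""
    dempster = combine_dempster(masses)
    factor = 1.0 + dempster.conflict_weight
    entries = {focal: m / factor for focal, m in dempster.fused.entries.items()}
    env = dempster.fused.environment_mass / factor
    deficit = 1.0 - sum(entries.values()) - env
    fused = MassFunction(entries=entries, environment_mass=env + deficit)
    return CombinationResult(
        fused=fused,
        conflict_mass=dempster.conflict_mass,
        conflict_weight=dempster.conflict_weight,
        rule="campos",
    )


def discount(mass: MassFunction, alpha: float) -> MassFunction:
    """Shafer discounting: scale every focal mass by alpha, the remainder
    joining the environment (a fully unreliable source, alpha = 0, becomes
    vacuous)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"discount weight must lie in [0, 1], got {alpha}")
    return MassFunction(
        entries={focal: alpha * m for focal, m in mass.entries.items() if m > 0},
        environment_mass=1.0 - alpha + alpha * mass.environment_mass,
    )


def combine_shafer(
    masses: Sequence[MassFunction],
    weights: Sequence[DiscountWeights] | Sequence[float],
) -> CombinationResult:
    """Shafer discount-and-average rule.

    Each source i is discounted by its reliability alpha_i, then the fused
    mass of every focal set is the plain arithmetic mean across sources.
    """
    if len(weights) != len(masses):
        raise ValueError("one discount weight per source is required")
    alphas = [w.alpha if isinstance(w, DiscountWeights) else float(w) for w in weights]
    discounted = [discount(m, a) for m, a in zip(masses, alphas)]
    n = len(discounted)
    entries: dict[FocalSet, float] = {}
    for dm in discounted:
        for focal, m in dm.entries.items():
            entries[focal] = entries.get(focal, 0.0) + m / n
    env = sum(dm.environment_mass for dm in discounted) / n
    fused = MassFunction(entries=entries, environment_mass=env)
    return CombinationResult(
        fused=fused, conflict_mass=0.0, conflict_weight=0.0, rule="shafer"
    )


def combine(
    masses: Sequence[MassFunction],
    rule: Rule,
    weights: Sequence[DiscountWeights] | Sequence[float] | None = None,
) -> CombinationResult:
    """Dispatch to a combination rule by name."""
    if rule == "dempster":
        return combine_dempster(masses)
    if rule == "yager":
        return combine_yager(masses)
    if rule == "campos":
        return combine_campos(masses)
    if rule == "shafer":
        if weights is None:
            weights = [1.0] * len(masses)
        return combine_shafer(masses, weights)
    raise ValueError(f"unknown combination rule: {rule}")


def bond_scores(result: CombinationResult) -> dict[BondHypothesis, float]:
    """Per-bond fused belief: the containment sum over focal sets holding
    the bond (environment excluded)."""
    scores: dict[BondHypothesis, float] = {}
    for focal, m in result.fused.entries.items():
        for b in focal:
            scores[b] = scores.get(b, 0.0) + m
    return scores
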