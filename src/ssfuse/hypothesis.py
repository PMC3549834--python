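"""Frame of discernment, focal subsets and basic belief assignment.

The frame theta is the set of primitive hypotheses — candidate disulfide
bonds — over which each method's evidence is expressed.  A basic belief
assignment (mass function) distributes unit belief over *consistent*
subsets of the frame (bond sets that form a matching) plus the
*environment*, the distinguished "anything else / ignorance" element that
absorbs unassigned belief.

The subset-scoring function turns a method's per-bond scores sigma_i into
a raw subset mass

    m(j) = max( sum_i (2 sigma_i + gamma_i - 1) / k, 0 )

with a correction gamma_i that amplifies extreme scores: for each member
bond i of subset j (k = |j|, S = sum of the members' sigma),

    gamma_i = -S / (2k)   if sigma_i = 0
    gamma_i = +S / (4k)   if sigma_i > 0.

Zero scores therefore drag a subset's mass down hard, high scores push it
up, and middling scores are only slightly modified.  Raw masses are then
normalised: if they total more than 1 they are scaled to sum to 1 and the
environment gets nothing; otherwise they are kept as-is and the deficit
1 - total is assigned to the environment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .core import BondHypothesis, EvidenceSet, is_consistent

#: Focal sets are frozensets of bonds; the environment is this sentinel.
FocalSet = frozenset  # frozenset[BondHypothesis]

SUM_TOLERANCE = 1e-9


@dataclass(frozen=True)
class Frame:
    """The frame of discernment for one protein.

    In ``union`` mode the hypotheses are the union of the bonds any method
    reported (how the case-study analysis proceeds); in ``all-pairs`` mode
    they are all n(n-1)/2 cysteine pairs.
    """

    protein_id: str
    hypotheses: tuple[BondHypothesis, ...]
    mode: Literal["union", "all-pairs"] = "union"

    def __post_init__(self) -> None:
        if len(set(self.hypotheses)) != len(self.hypotheses):
            raise ValueError("frame hypotheses must be unique")

    def __len__(self) -> int:
        return len(self.hypotheses)

    def __contains__(self, b: BondHypothesis) -> bool:
        return b in self.hypotheses


@dataclass
class MassFunction:
    """A basic belief assignment over consistent focal subsets plus the
    environment.

    ``entries`` maps non-empty focal sets to mass; ``environment_mass`` is
    the belief left to ignorance.  Masses are non-negative and total 1.
    """

    entries: dict[FocalSet, float] = field(default_factory=dict)
    environment_mass: float = 0.0

    def __post_init__(self) -> None:
        self.entries = {FocalSet(k): float(v) for k, v in self.entries.items()}
        self.validate()

    def validate(self) -> None:
        for focal, mass in self.entries.items():
            if not focal:
                raise ValueError("the empty set cannot carry mass")
            if mass < -SUM_TOLERANCE:
                raise ValueError(f"negative mass {mass} on {set(focal)}")
        if self.environment_mass < -SUM_TOLERANCE:
            raise ValueError(f"negative environment mass {self.environment_mass}")
        total = sum(self.entries.values()) + self.environment_mass
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"masses must sum to 1, got {total}")

    def mass(self, focal: Iterable[BondHypothesis]) -> float:
        return self.entries.get(FocalSet(focal), 0.0)

    def focal_sets(self) -> list[FocalSet]:
        return list(self.entries)

    @classmethod
    def from_singleton_scores(
        cls, scores: Mapping[BondHypothesis, float]
    ) -> "MassFunction":
        """Build a mass function over singleton focal sets, scaling the
        scores to total mass 1 (the construction used for the conflicting
        two-method illustration on 1G6X)."""
        total = float(sum(scores.values()))
        if total <= 0:
            raise ValueError("scores must have positive total")
        return cls(
            entries={FocalSet([b]): s / total for b, s in scores.items() if s > 0}
        )


def build_frame(
    evidence_sets: list[EvidenceSet],
    mode: Literal["union", "all-pairs"] = "union",
    cys_positions: Iterable[int] | None = None,
) -> Frame:
    """Build the frame of discernment from the methods' reported bonds.

    Union mode takes the union of all reported bonds in first-report order;
    all-pairs mode requires ``cys_positions`` and enumerates every pair.
    All evidence sets must refer to the same protein.
    """
    if not evidence_sets:
        raise ValueError("at least one evidence set is required")
    pids = {s.protein_id for s in evidence_sets}
    if len(pids) > 1:
        raise ValueError(f"evidence sets refer to different proteins: {sorted(pids)}")
    protein_id = evidence_sets[0].protein_id
    if mode == "all-pairs":
        if cys_positions is None:
            raise ValueError("all-pairs mode requires the protein's cysteine positions")
        pos = sorted(cys_positions)
        hyps = tuple(
            BondHypothesis(pos[i], pos[j])
            for i in range(len(pos))
            for j in range(i + 1, len(pos))
        )
        return Frame(protein_id=protein_id, hypotheses=hyps, mode="all-pairs")
    seen: list[BondHypothesis] = []
    for s in evidence_sets:
        for ev in s.items:
            if ev.bond not in seen:
                seen.append(ev.bond)
    if not seen:
        raise ValueError("no bonds reported by any method; frame would be empty")
    return Frame(protein_id=protein_id, hypotheses=tuple(seen), mode="union")


def enumerate_consistent_subsets(frame: Frame, max_card: int = 4) -> list[FocalSet]:
    """All non-empty subsets of the frame up to ``max_card`` bonds whose
    members form a matching.

    Subsets in which two bonds share a cysteine are *inconsistent* — they
    cannot coexist in a topology — and carry zero mass by definition, so
    they are excluded here rather than enumerated and zeroed.
    """
    if max_card < 1:
        raise ValueError("max_card must be >= 1")
    out: list[FocalSet] = []
    for r in range(1, min(max_card, len(frame.hypotheses)) + 1):
        for combo in itertools.combinations(frame.hypotheses, r):
            if is_consistent(combo):
                out.append(FocalSet(combo))
    return out


def raw_subset_score(scores: Iterable[float]) -> float:
    """Raw (pre-normalisation) subset mass from the member bonds' scores."""
    sigma = list(scores)
    k = len(sigma)
    if k == 0:
        raise ValueError("a focal subset must contain at least one bond")
    total = sum(sigma)
    acc = 0.0
    for s in sigma:
        gamma = -total / (2 * k) if s == 0 else total / (4 * k)
        acc += (2 * s + gamma - 1) / k
    return max(acc, 0.0)


def assign_masses(
    frame: Frame, evidence: EvidenceSet, subsets: list[FocalSet] | None = None
) -> MassFunction:
    """Convert one method's per-bond beliefs into a mass function.

    Bonds of the frame the method did not report score sigma = 0.  Raw
    subset masses are normalised as described in the module docstring; a
    method whose every subset scores 0 yields the vacuous mass function
    (environment = 1).
    """
    for ev in evidence.items:
        if ev.bond not in frame:
            raise ValueError(f"evidence bond {ev.bond} is not in the frame")
    if subsets is None:
        subsets = enumerate_consistent_subsets(frame)
    raw: dict[FocalSet, float] = {}
    for subset in subsets:
        score = raw_subset_score(evidence.belief_of(b) for b in sorted(subset))
        if score > 0:
            raw[subset] = score
    total = sum(raw.values())
    if total > 1.0:
        entries = {focal: score / total for focal, score in raw.items()}
        environment = 0.0
    else:
        entries = raw
        environment = 1.0 - total
    return MassFunction(entries=entries, environment_mass=environment)


def belief_of(mass: MassFunction, subset: Iterable[BondHypothesis]) -> float:
    """Belief: total mass of focal sets contained in ``subset``."""
    target = FocalSet(subset)
    return sum(m for focal, m in mass.entries.items() if focal <= target)


def plausibility_of(mass: MassFunction, subset: Iterable[BondHypothesis]) -> float:
    """Plausibility: total mass of focal sets intersecting ``subset``.

    The environment intersects every non-empty subset, so its mass always
    counts; belief_of(A) <= plausibility_of(A) for every A.
    """
    target = FocalSet(subset)
    if not target:
        return 0.0
    pl = sum(m for focal, m in mass.entries.items() if focal & target)
    return pl + mass.environment_mass
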