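"""Domain types shared across the package.

A protein's disulfide connectivity is modelled as a matching on its
cysteines: each candidate bond is an unordered pair of cysteine residue
positions, and a valid topology never reuses a cysteine.  Evidence about a
bond is a belief score in [0, 1] attached by one of several determination
methods (tandem-MS scoring, SVM sequence prediction, cysteine-separation
profile matching, or any external tool).

All residue numbering is 1-based, matching the convention used for bond
labels in the literature (C5-C55 and so on).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


class TopologyError(ValueError):
    """A bond set violates the matching property (shared cysteine)."""


@dataclass(frozen=True, order=True)
class BondHypothesis:
    """An unordered pair of cysteine residue positions (1-based).

    Stored canonically with ``cys_a < cys_b``; construct through
    :func:`bond` to canonicalise arbitrary input order.
    """

    cys_a: int
    cys_b: int

    def __post_init__(self) -> None:
        if self.cys_a == self.cys_b:
            raise ValueError(f"bond cannot link a cysteine to itself: {self.cys_a}")
        if self.cys_a > self.cys_b:
            raise ValueError(
                f"bond positions must be ordered cys_a < cys_b, got "
                f"({self.cys_a}, {self.cys_b}); use bond() to canonicalise"
            )

    @property
    def cysteines(self) -> frozenset[int]:
        return frozenset((self.cys_a, self.cys_b))

    def shares_cysteine(self, other: "BondHypothesis") -> bool:
        return bool(self.cysteines & other.cysteines)

    def __str__(self) -> str:  # e.g. "C14-C31"
        return f"C{self.cys_a}-C{self.cys_b}"


def bond(a: int, b: int) -> BondHypothesis:
    """Canonical bond constructor: order-insensitive."""
    if a > b:
        a, b = b, a
    return BondHypothesis(a, b)


@dataclass(frozen=True)
class Protein:
    """A protein sequence with the positions of its cysteines.

    ``cys_positions`` are 1-based indices into ``sequence`` and are derived
    from the sequence unless given explicitly (in which case they are
    validated against it).
    """

    id: str
    sequence: str
    cys_positions: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cys_positions is None:
            derived = tuple(
                i + 1 for i, aa in enumerate(self.sequence) if aa.upper() == "C"
            )
            object.__setattr__(self, "cys_positions", derived)
            return
        object.__setattr__(self, "cys_positions", tuple(self.cys_positions))
        prev = 0
        for pos in self.cys_positions:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"{self.id}: cysteine position {pos} outside sequence "
                    f"of length {len(self.sequence)}"
                )
            if self.sequence[pos - 1].upper() != "C":
                raise ValueError(
                    f"{self.id}: residue at position {pos} is "
                    f"{self.sequence[pos - 1]!r}, not a cysteine"
                )
            if pos <= prev:
                raise ValueError(f"{self.id}: cysteine positions must be strictly increasing")
            prev = pos

    @property
    def n_cysteines(self) -> int:
        return len(self.cys_positions)

    def all_pairs(self) -> list[BondHypothesis]:
        """All n(n-1)/2 candidate bonds between this protein's cysteines."""
        pos = self.cys_positions
        return [bond(pos[i], pos[j]) for i in range(len(pos)) for j in range(i + 1, len(pos))]


@dataclass(frozen=True)
class Evidence:
    """One method's belief in one bond hypothesis."""

    bond: BondHypothesis
    belief: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.belief <= 1.0:
            raise ValueError(f"belief must lie in [0, 1], got {self.belief}")


@dataclass
class EvidenceSet:
    """One method's reported connectivity for one protein.

    Mirrors the per-method output set D_k = {(C_i, C_j, sigma_k)}: a list of
    bond/belief triplets from a single source.  Bonds must be unique within
    the set.
    """

    protein_id: str
    method: str
    items: list[Evidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[BondHypothesis] = set()
        for ev in self.items:
            if ev.bond in seen:
                raise ValueError(
                    f"duplicate bond {ev.bond} in evidence set "
                    f"({self.protein_id}, {self.method})"
                )
            seen.add(ev.bond)

    def __iter__(self) -> Iterator[Evidence]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def bonds(self) -> list[BondHypothesis]:
        return [ev.bond for ev in self.items]

    def belief_of(self, b: BondHypothesis) -> float:
        """Belief for bond ``b``; 0 if this method did not report it."""
        for ev in self.items:
            if ev.bond == b:
                return ev.belief
        return 0.0


@dataclass(frozen=True)
class Topology:
    """A set of disulfide bonds forming a matching on cysteines."""

    bonds: frozenset[BondHypothesis]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bonds", frozenset(self.bonds))
        validate_matching(self.bonds)

    def __iter__(self) -> Iterator[BondHypothesis]:
        return iter(sorted(self.bonds))

    def __len__(self) -> int:
        return len(self.bonds)

    def __contains__(self, b: BondHypothesis) -> bool:
        return b in self.bonds


def validate_matching(bonds: Iterable[BondHypothesis]) -> None:
    """Raise :class:`TopologyError` naming the clashing bonds if any two
    bonds share a cysteine."""
    used: dict[int, BondHypothesis] = {}
    for b in sorted(bonds):
        for cys in (b.cys_a, b.cys_b):
            if cys in used:
                raise TopologyError(
                    f"bonds {used[cys]} and {b} share cysteine C{cys}"
                )
            used[cys] = b


def validate_topology(bonds: Iterable[BondHypothesis]) -> Topology:
    """Validate the matching property and wrap the bonds as a Topology."""
    return Topology(frozenset(bonds))


def is_consistent(bonds: Iterable[BondHypothesis]) -> bool:
    """True if no two bonds share a cysteine (a consistent bond subset)."""
    seen: set[int] = set()
    for b in bonds:
        if b.cys_a in seen or b.cys_b in seen:
            return False
        seen.add(b.cys_a)
        seen.add(b.cys_b)
    return True
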