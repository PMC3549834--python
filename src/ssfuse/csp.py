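"""Cysteine-separation-profile (CSP) connectivity prediction.

Proteins with similar disulfide bonding patterns tend to share folds, and
the gaps between consecutive cysteines capture enough of the fold for a
nearest-profile lookup: a query protein inherits the annotated topology of
the reference protein whose separation profile is closest in L1 distance
(the *divergence* D).  The transferred bonds carry the belief

    sigma_CSP = (1 + log10(1 + D/10))^-2,

which is 1 at D = 0 and decays slowly with divergence.

Reference entries store their topology by cysteine *ordinal* (k-th
cysteine), since the profile abstracts positions away; transfer maps
ordinals onto the query's cysteine positions.  Profiles of different
length (different cysteine counts) are incomparable.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

from .core import BondHypothesis, Evidence, EvidenceSet, Protein, Topology, bond


class ProfileError(ValueError):
    pass


class IncomparableProfiles(ValueError):
    """Profiles with different cysteine counts cannot be compared."""


@dataclass(frozen=True)
class CSProfile:
    """Ordered consecutive cysteine-position differences of one protein."""

    protein_id: str
    separations: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.separations):
            raise ProfileError(f"{self.protein_id}: separations must be >= 1")

    def __len__(self) -> int:
        return len(self.separations)


@dataclass(frozen=True)
class ReferenceEntry:
    """A reference protein: its profile and annotated topology by ordinal.

    ``ordinal_bonds`` pairs are 1-based cysteine ordinals (1 = first
    cysteine in sequence); they must form a matching.
    """

    protein_id: str
    cys_positions: tuple[int, ...]
    ordinal_bonds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.cys_positions)
        seen: set[int] = set()
        for a, b in self.ordinal_bonds:
            if not (1 <= a <= n and 1 <= b <= n) or a == b:
                raise ValueError(f"{self.protein_id}: bad ordinal bond ({a}, {b})")
            if a in seen or b in seen:
                raise ValueError(f"{self.protein_id}: ordinal bonds share a cysteine")
            seen.update((a, b))

    @property
    def profile(self) -> CSProfile:
        return CSProfile(
            protein_id=self.protein_id,
            separations=tuple(
                b - a for a, b in zip(self.cys_positions, self.cys_positions[1:])
            ),
        )

    def topology_at(self, cys_positions: tuple[int, ...]) -> Topology:
        """Map the ordinal annotation onto concrete cysteine positions."""
        return Topology(
            frozenset(
                bond(cys_positions[a - 1], cys_positions[b - 1])
                for a, b in self.ordinal_bonds
            )
        )


@dataclass(frozen=True)
class CSPMatch:
    """The best reference hit: entry, divergence D, belief, and how many
    entries tied at the minimal divergence (feeds discounting)."""

    entry: ReferenceEntry
    divergence: float
    belief: float
    n_best_matches: int


def compute_profile(protein: Protein) -> CSProfile:
    """Separation profile of a protein; needs at least two cysteines."""
    pos = protein.cys_positions
    if len(pos) < 2:
        raise ProfileError(
            f"{protein.id}: a separation profile needs >= 2 cysteines, got {len(pos)}"
        )
    return CSProfile(
        protein_id=protein.id,
        separations=tuple(b - a for a, b in zip(pos, pos[1:])),
    )


def divergence(x: CSProfile, y: CSProfile) -> float:
    """L1 distance between two equal-length separation profiles."""
    if len(x) != len(y):
        raise IncomparableProfiles(
            f"profiles of length {len(x)} and {len(y)} are incomparable"
        )
    return float(sum(abs(a - b) for a, b in zip(x.separations, y.separations)))


def csp_belief(d: float) -> float:
    """Belief from divergence: (1 + log10(1 + D/10))^-2, in (0, 1]."""
    if d < 0:
        raise ValueError("divergence must be non-negative")
    return (1.0 + math.log10(1.0 + d / 10.0)) ** -2


def predict_topology(
    protein: Protein, db: list[ReferenceEntry]
) -> tuple[EvidenceSet, CSPMatch | None]:
    """Transfer the topology of the nearest reference profile.

    Only entries with the same cysteine count are comparable; among those,
    the minimal-divergence entry wins, ties broken by database order (the
    tie count is surfaced for discounting).  With no comparable entry the
    evidence set is empty and the match is None.
    """
    if not db:
        raise ValueError("reference database is empty")
    query = compute_profile(protein)
    best: ReferenceEntry | None = None
    best_d = math.inf
    ties = 0
    for entry in db:
        try:
            d = divergence(query, entry.profile)
        except IncomparableProfiles:
            continue
        if d < best_d:
            best, best_d, ties = entry, d, 1
        elif d == best_d:
            ties += 1
    if best is None:
        return EvidenceSet(protein_id=protein.id, method="CSP", items=[]), None
    belief = csp_belief(best_d)
    topology = best.topology_at(protein.cys_positions)
    items = [Evidence(bond=b, belief=belief, method="CSP") for b in topology]
    match = CSPMatch(entry=best, divergence=best_d, belief=belief, n_best_matches=ties)
    return EvidenceSet(protein_id=protein.id, method="CSP", items=items), match


def read_reference_db(path: str | os.PathLike) -> list[ReferenceEntry]:
    """Read a reference DB TSV: protein_id, cys_positions (comma-joined),
    bonds (ordinal pairs ``a-b``, comma-joined; empty for no bonds)."""
    entries: list[ReferenceEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_id", "cys_positions", "bonds"]:
            raise ValueError(f"{path}: bad reference DB header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, pos_s, bonds_s = line.split("\t")[:3]
            positions = tuple(int(p) for p in pos_s.split(",") if p)
            obonds = tuple(
                tuple(int(x) for x in pair.split("-"))  # type: ignore[misc]
                for pair in bonds_s.split(",")
                if pair
            )
            entries.append(
                ReferenceEntry(
                    protein_id=pid, cys_positions=positions, ordinal_bonds=obonds
                )
            )
    return entries


def write_reference_db(entries: list[ReferenceEntry], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcys_positions\tbonds\n")
        for e in entries:
            pos = ",".join(str(p) for p in e.cys_positions)
            bonds_s = ",".join(f"{a}-{b}" for a, b in e.ordinal_bonds)
            fh.write(f"{e.protein_id}\t{pos}\t{bonds_s}\n")
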