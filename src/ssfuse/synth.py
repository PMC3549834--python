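"""Seeded synthetic data: proteins, planted topologies, evidence, spectra.

The generator emulates the study conditions of a multi-method disulfide
mapping experiment: proteins with an even number of cysteines carrying a
planted perfect-matching topology; several methods reporting the planted
bonds with high (but noisy) beliefs, occasionally dropping a bond, and
occasionally reporting a *conflicting* decoy — a bond sharing a cysteine
with a true bond, the hardest kind of false positive for fusion.  Belief
spreads mirror the range observed in published per-bond scores: true
bonds around 0.85, decoys around 0.2.

Everything is a pure function of (config, seed): identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BondHypothesis, Evidence, EvidenceSet, Protein, Topology, bond
from .ms import MONO_H, DisulfidePair, Spectrum, enumerate_pairs, theoretical_fragments

_AA_NO_CKR = "ADEFGHILMNPQSTVWY"  # no C (placed explicitly), no K/R (cleavage)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic-evidence generator.

    true_belief_mean/decoy_belief_mean with belief_concentration set the
    Beta distributions beliefs are drawn from; dropout is the per-method
    chance of missing a planted bond; conflict_rate the per-method chance
    of adding a decoy sharing a cysteine with a planted bond.
    """

    n_proteins: int = 20
    n_cysteines_min: int = 4
    n_cysteines_max: int = 10
    seed: int = 0
    methods: tuple[str, ...] = ("MS", "SVM", "CSP")
    true_belief_mean: float = 0.85
    decoy_belief_mean: float = 0.20
    belief_concentration: float = 25.0
    dropout: float = 0.10
    conflict_rate: float = 0.20

    def __post_init__(self) -> None:
        for name in ("true_belief_mean", "decoy_belief_mean", "dropout", "conflict_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_cysteines_min < 2 or self.n_cysteines_max < self.n_cysteines_min:
            raise ValueError("need 2 <= n_cysteines_min <= n_cysteines_max")
        if self.n_cysteines_min % 2 or self.n_cysteines_max % 2:
            raise ValueError(
                "cysteine counts must be even: a full matching topology "
                "pairs every cysteine"
            )


def _beta_belief(rng: np.random.Generator, mean: float, conc: float) -> float:
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    return float(rng.beta(mean * conc, (1 - mean) * conc))


def _random_protein(rng: np.random.Generator, pid: str, n_cys: int) -> Protein:
    length = n_cys * 12 + int(rng.integers(6, 20))
    # place cysteines on a jittered grid, keeping >= 3 residues apart
    positions = sorted(
        rng.choice(np.arange(3, length - 2, 3), size=n_cys, replace=False)
    )
    seq = list(rng.choice(list(_AA_NO_CKR), size=length))
    # sprinkle tryptic sites so digestion yields several peptides
    for i in range(8, length - 1, 9):
        if (i + 1) not in positions:
            seq[i] = "K" if rng.random() < 0.5 else "R"
    for pos in positions:
        seq[pos - 1] = "C"
    return Protein(id=pid, sequence="".join(seq))


def _planted_topology(rng: np.random.Generator, protein: Protein) -> Topology:
    order = list(rng.permutation(protein.cys_positions))
    bonds = [bond(order[i], order[i + 1]) for i in range(0, len(order), 2)]
    return Topology(frozenset(bonds))


def generate(
    sim: SimConfig,
) -> tuple[list[Protein], dict[str, Topology], list[EvidenceSet]]:
    """Generate proteins, planted topologies and per-method evidence.

    Returns (proteins, topology per protein id, evidence sets — one per
    (protein, method) with at least one reported bond).
    """
    rng = np.random.default_rng(sim.seed)
    proteins: list[Protein] = []
    topologies: dict[str, Topology] = {}
    evidence_sets: list[EvidenceSet] = []
    for i in range(sim.n_proteins):
        n_cys = int(
            rng.integers(sim.n_cysteines_min // 2, sim.n_cysteines_max // 2 + 1) * 2
        )
        protein = _random_protein(rng, f"SYN{i:03d}", n_cys)
        topo = _planted_topology(rng, protein)
        proteins.append(protein)
        topologies[protein.id] = topo
        true_bonds = sorted(topo.bonds)
        decoy_pool = sorted(set(protein.all_pairs()) - topo.bonds)
        for method in sim.methods:
            items: list[Evidence] = []
            reported: set[BondHypothesis] = set()
            for b in true_bonds:
                if rng.random() < sim.dropout:
                    continue
                belief = _beta_belief(rng, sim.true_belief_mean, sim.belief_concentration)
                items.append(Evidence(bond=b, belief=belief, method=method))
                reported.add(b)
            if decoy_pool and rng.random() < sim.conflict_rate:
                anchor = true_bonds[int(rng.integers(len(true_bonds)))]
                conflicting = [
                    d for d in decoy_pool
                    if d.shares_cysteine(anchor) and d not in reported
                ]
                if conflicting:
                    d = conflicting[int(rng.integers(len(conflicting)))]
                    belief = _beta_belief(
                        rng, sim.decoy_belief_mean, sim.belief_concentration
                    )
                    items.append(Evidence(bond=d, belief=belief, method=method))
            if items:
                evidence_sets.append(
                    EvidenceSet(protein_id=protein.id, method=method, items=items)
                )
    return proteins, topologies, evidence_sets


def synth_spectra(
    protein: Protein,
    topology: Topology,
    noise_fraction: float = 0.0,
    seed: int = 0,
    base_intensity: float = 100.0,
) -> list[Spectrum]:
    """One MS/MS spectrum per planted bond, built from its own theoretical
    fragments plus uniform-random noise peaks.

    ``noise_fraction`` is the fraction of the final peak list that is
    noise (0.5 means as many noise peaks as signal peaks); noise
    intensities sit between 20% and 100% of the signal intensity so they
    survive the usual 10% intensity floor.
    """
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    pairs = enumerate_pairs(protein, "trypsin", missed_cleavages=1)
    by_bond: dict[BondHypothesis, DisulfidePair] = {}
    for pair in pairs:
        by_bond.setdefault(pair.bond, pair)
    spectra: list[Spectrum] = []
    for b in sorted(topology.bonds):
        pair = by_bond.get(b)
        if pair is None:
            continue  # bond not representable under this digestion
        theo = theoretical_fragments(pair)
        signal = sorted({round(f.mz, 4) for f in theo.fragments})
        peaks = [(mz, base_intensity * float(rng.uniform(0.6, 1.0))) for mz in signal]
        if noise_fraction > 0:
            n_noise = int(round(len(signal) * noise_fraction / (1 - noise_fraction)))
            lo, hi = min(signal) * 0.8, max(signal) * 1.1
            for _ in range(n_noise):
                peaks.append(
                    (
                        float(rng.uniform(lo, hi)),
                        base_intensity * float(rng.uniform(0.2, 1.0)),
                    )
                )
        spectra.append(
            Spectrum(
                precursor_mass=pair.mass,
                precursor_charge=1,
                peaks=peaks,
                title=f"{protein.id}|{b}",
            )
        )
    return spectra
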