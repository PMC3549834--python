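"""Tandem-MS scoring of candidate disulfide-bonded peptide pairs.

The workflow mirrors a non-reduced MS/MS disulfide-mapping experiment:
the protein is digested in silico, every cysteine-containing peptide pair
(joined by a putative S-S bridge, losing two hydrogens) forms a candidate
whose mass is checked against the precursor; surviving candidates are
fragmented in silico under an expanded ion-type model (a, a-H2O, a-NH3,
b, b-H2O, b-NH3, c, x, y, y-H2O, y-NH3, z) and the theoretical fragments
are matched to the spectrum's peaks.

Scores per candidate:

- VS: intensity-weighted fraction of retained peaks explained by a
  confirmatory match, scaled to [0, 100].
- pp: -log10 of the binomial upper-tail probability that at least the
  observed number of fragment confirmations arose by chance, with
  per-fragment random-match probability p2 = 2 m VM_TH / r (m theoretical
  fragments, VM_TH the match tolerance, r the spectral m/z range).
- pp2: -log10 of the Gaussian upper tail of the total matched abundance,
  against a mean/variance estimated from the spectrum's own retained peak
  intensities.

The search space of candidate masses can be trimmed with the classic
subset-sum approximation: a removed mass always has a kept representative
within a relative factor (1 + epsilon).  The global topology is the
maximum-weight matching over per-bond scores.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from pyteomics import mass as pmass
from pyteomics import mgf as pmgf
from pyteomics import parser as pparser
from scipy import special, stats

from .core import BondHypothesis, Protein, Topology, bond

PROTON = 1.00727646688
MONO_H = 1.0078250319
AVG_H = 1.00794

ION_TYPES = (
    "a", "a-H2O", "a-NH3",
    "b", "b-H2O", "b-NH3",
    "c",
    "x",
    "y", "y-H2O", "y-NH3",
    "z",
)
_N_TERMINAL = {"a", "a-H2O", "a-NH3", "b", "b-H2O", "b-NH3", "c"}

CLEAVAGE_RULES = {
    "trypsin": pparser.expasy_rules["trypsin"],
    "chymotrypsin": pparser.expasy_rules["chymotrypsin high specificity"],
}


@dataclass
class MSConfig:
    """Knobs for matching and scoring.

    tolerance: fragment match tolerance in Da (default 0.5).
    intensity_floor: fraction of the maximum intensity below which peaks
        are ignored (default 0.10, the usual noise threshold).
    precursor_tolerance: Da window for candidate/precursor agreement.
    epsilon: relative trimming parameter for the subset-sum search-space
        reduction.
    pp_max: pp value mapped to belief 1.0 (beliefs are min(pp/pp_max, 1);
        a convention for putting pp on the [0, 1] belief scale).
    """

    tolerance: float = 0.5
    intensity_floor: float = 0.1
    precursor_tolerance: float = 1.0
    epsilon: float = 1e-4
    pp_max: float = 100.0


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide with its 1-based location in the protein."""

    sequence: str
    start: int  # 1-based position of the first residue

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    @property
    def cys_positions(self) -> tuple[int, ...]:
        return tuple(
            self.start + i for i, aa in enumerate(self.sequence) if aa == "C"
        )

    @property
    def mono_mass(self) -> float:
        return float(pmass.fast_mass(self.sequence))

    def sequence_range(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class DisulfidePair:
    """Two peptides (possibly the same one) joined by a disulfide bridge."""

    peptide_a: Peptide
    peptide_b: Peptide
    bond: BondHypothesis

    def __post_init__(self) -> None:
        if self.bond.cys_a not in self.peptide_a.cys_positions:
            raise ValueError(f"peptide A does not contain C{self.bond.cys_a}")
        if self.bond.cys_b not in self.peptide_b.cys_positions:
            raise ValueError(f"peptide B does not contain C{self.bond.cys_b}")

    @property
    def intra(self) -> bool:
        return self.peptide_a == self.peptide_b

    @property
    def mass(self) -> float:
        """Monoisotopic mass of the linked structure (loses 2 H)."""
        if self.intra:
            return self.peptide_a.mono_mass - 2 * MONO_H
        return self.peptide_a.mono_mass + self.peptide_b.mono_mass - 2 * MONO_H


@dataclass(frozen=True)
class Fragment:
    ion_type: str
    mz: float
    source: str  # "a" or "b": which peptide's backbone was cleaved

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


@dataclass
class TheoreticalFragmentSet:
    pair: DisulfidePair
    fragments: list[Fragment]

    def __len__(self) -> int:
        return len(self.fragments)

    def mz_array(self) -> np.ndarray:
        return np.array(sorted(f.mz for f in self.fragments))


@dataclass
class Spectrum:
    """An MS/MS spectrum: neutral precursor mass, charge and peak list."""

    precursor_mass: float
    precursor_charge: int
    peaks: list[tuple[float, float]]  # (m/z, intensity), sorted by m/z
    title: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be non-negative")


@dataclass
class MatchReport:
    """Scores for one candidate bond against one spectrum."""

    bond: BondHypothesis
    vs_score: float
    pp: float
    pp2: float
    precursor_mass: float
    n_match: int
    n_theoretical: int


def digest(
    protein: Protein,
    protease: Literal["trypsin", "chymotrypsin"] = "trypsin",
    missed_cleavages: int = 0,
) -> list[Peptide]:
    """In-silico digestion preserving peptide locations."""
    if protease not in CLEAVAGE_RULES:
        raise ValueError(
            f"unsupported protease {protease!r}; choose from {sorted(CLEAVAGE_RULES)}"
        )
    rule = CLEAVAGE_RULES[protease]
    peptides = [
        Peptide(sequence=seq, start=start + 1)
        for start, seq in pparser.icleave(
            protein.sequence, rule, missed_cleavages=missed_cleavages
        )
        if seq
    ]
    return sorted(peptides, key=lambda p: (p.start, p.end))


def enumerate_pairs(
    protein: Protein,
    protease: Literal["trypsin", "chymotrypsin"] = "trypsin",
    missed_cleavages: int = 0,
) -> list[DisulfidePair]:
    """All disulfide-bonded peptide structures for the protein.

    Every cysteine of one peptide paired with every cysteine of another
    (or of the same peptide, for intra-peptide bonds), one candidate per
    (peptide pair, bond) combination.
    """
    peptides = [p for p in digest(protein, protease, missed_cleavages) if p.cys_positions]
    pairs: list[DisulfidePair] = []
    for i, pa in enumerate(peptides):
        # intra-peptide bonds
        for ca, cb in itertools.combinations(pa.cys_positions, 2):
            pairs.append(DisulfidePair(peptide_a=pa, peptide_b=pa, bond=bond(ca, cb)))
        for pb in peptides[i + 1 :]:
            if set(pa.sequence_range()) & set(pb.sequence_range()):
                continue  # overlapping missed-cleavage forms of the same region
            for ca in pa.cys_positions:
                for cb in pb.cys_positions:
                    if ca == cb:
                        continue
                    if ca < cb:
                        pairs.append(
                            DisulfidePair(peptide_a=pa, peptide_b=pb, bond=bond(ca, cb))
                        )
                    else:
                        pairs.append(
                            DisulfidePair(peptide_a=pb, peptide_b=pa, bond=bond(ca, cb))
                        )
    return pairs


def trim_search_space(masses: Sequence[float], epsilon: float) -> list[float]:
    """Subset-sum style trimming of an ascending mass list.

    Greedy scan: keep an element only when it exceeds (1 + epsilon) times
    the last kept element.  Every removed mass DMS_i then has a kept
    representative DMS* with DMS_i / (1 + epsilon) <= DMS* <= DMS_i.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if any(b < a for a, b in zip(masses, masses[1:])):
        raise ValueError("masses must be sorted ascending")
    kept: list[float] = []
    for m in masses:
        if not kept or m > kept[-1] * (1.0 + epsilon):
            kept.append(m)
    return kept


def theoretical_fragments(pair: DisulfidePair) -> TheoreticalFragmentSet:
    """Singly-charged monoisotopic fragments under the expanded ion model.

    Backbone fragments of each peptide are generated for every cleavage
    site; a fragment retaining the bonded cysteine carries the intact
    partner peptide (mass - 2 H) attached through the bridge.  For
    intra-peptide bonds only fragments containing both or neither
    cysteine are generated (a single-cysteine fragment would leave the
    ring open, which the model does not attempt to describe).
    """
    fragments: list[Fragment] = []
    if pair.intra:
        pep = pair.peptide_a
        for ion_type, site, mz in _backbone_fragments(pep):
            retained = _retained_positions(pep, ion_type, site)
            n_cys = len({pair.bond.cys_a, pair.bond.cys_b} & retained)
            if n_cys == 1:
                continue
            if n_cys == 2:
                mz -= 2 * MONO_H
            fragments.append(Fragment(ion_type=ion_type, mz=mz, source="a"))
        return TheoreticalFragmentSet(pair=pair, fragments=fragments)
    specs = (
        (pair.peptide_a, pair.bond.cys_a, pair.peptide_b, "a"),
        (pair.peptide_b, pair.bond.cys_b, pair.peptide_a, "b"),
    )
    for pep, own_cys, partner, tag in specs:
        partner_mass = partner.mono_mass - 2 * MONO_H
        for ion_type, site, mz in _backbone_fragments(pep):
            if own_cys in _retained_positions(pep, ion_type, site):
                mz = mz + partner_mass
            fragments.append(Fragment(ion_type=ion_type, mz=mz, source=tag))
    return TheoreticalFragmentSet(pair=pair, fragments=fragments)


def _backbone_fragments(pep: Peptide) -> list[tuple[str, int, float]]:
    """(ion_type, cleavage site index, singly-charged m/z) for all sites.

    Site i (1 <= i < len) splits the peptide into prefix [:i] and suffix
    [i:]; N-terminal ion series use the prefix, C-terminal the suffix.
    """
    out: list[tuple[str, int, float]] = []
    n = len(pep.sequence)
    for i in range(1, n):
        prefix, suffix = pep.sequence[:i], pep.sequence[i:]
        for ion_type in ION_TYPES:
            sub = prefix if ion_type in _N_TERMINAL else suffix
            mz = float(pmass.fast_mass(sub, ion_type=ion_type, charge=1))
            if mz > 0:
                out.append((ion_type, i, mz))
    return out


def _retained_positions(pep: Peptide, ion_type: str, site: int) -> set[int]:
    if ion_type in _N_TERMINAL:
        return set(range(pep.start, pep.start + site))
    return set(range(pep.start + site, pep.end + 1))


def filter_by_precursor(
    pairs: Iterable[DisulfidePair], precursor_mass: float, tolerance: float = 1.0
) -> list[DisulfidePair]:
    """Keep candidates whose linked mass agrees with the precursor."""
    return [p for p in pairs if abs(p.mass - precursor_mass) <= tolerance]


def p2_of(m: int, vm_th: float, r: float) -> float:
    """Random per-peak match probability p2 = 2 m VM_TH / r.

    ``m`` is the number of theoretical fragment ions, VM_TH the match
    tolerance (Da) and r the spectrum's m/z detection range.  Values at or
    above 1 are clamped just below it; non-positive inputs are errors.
    """
    if m <= 0 or vm_th <= 0 or r <= 0:
        raise ValueError("m, VM_TH and r must all be positive")
    p2 = 2.0 * m * vm_th / r
    if p2 >= 1.0:
        p2 = 1.0 - 1e-9
    return p2


def pp_score(n: int, n_match: int, p2: float) -> float:
    """-log10 binomial upper tail of >= n_match random matches among n."""
    if not 0 <= n_match <= n:
        raise ValueError("need 0 <= n_match <= n")
    if not 0.0 < p2 < 1.0:
        raise ValueError(f"p2 must lie strictly in (0, 1), got {p2}")
    if n_match == 0:
        return 0.0
    # sum the tail in log space: logsf underflows for extreme match counts
    log_terms = stats.binom.logpmf(np.arange(n_match, n + 1), n, p2)
    log_tail = float(special.logsumexp(log_terms))
    return float(-log_tail / math.log(10.0))


def pp2_score(i_match: float, mu: float, sigma: float) -> float:
    """-log10 Gaussian upper tail of the total matched abundance."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    log_tail = stats.norm.logsf(i_match, loc=mu, scale=sigma)
    return float(-log_tail / math.log(10.0))


def match_score_vs(
    spectrum: Spectrum,
    theoretical: TheoreticalFragmentSet,
    tolerance: float = 0.5,
    intensity_floor: float = 0.1,
) -> MatchReport:
    """Match theoretical fragments to the spectrum and score the candidate.

    Peaks below ``intensity_floor`` of the maximum intensity are ignored.
    VS is the matched fraction of retained peak intensity x 100; pp and
    pp2 quantify how unlikely the match count and matched abundance are
    under random matching (mean/s.d. for pp2 estimated from the retained
    peak intensities themselves).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if len(theoretical) == 0:
        raise ValueError("theoretical fragment set is empty")
    if not spectrum.peaks:
        return MatchReport(
            bond=theoretical.pair.bond,
            vs_score=0.0, pp=0.0, pp2=0.0,
            precursor_mass=spectrum.precursor_mass,
            n_match=0, n_theoretical=len(theoretical),
        )
    mz = np.array([p[0] for p in spectrum.peaks])
    inten = np.array([p[1] for p in spectrum.peaks])
    max_i = inten.max()
    keep = inten >= intensity_floor * max_i if max_i > 0 else inten >= 0
    mz, inten = mz[keep], inten[keep]
    theo = theoretical.mz_array()
    # peak -> nearest theoretical fragment
    idx = np.searchsorted(theo, mz)
    dist = np.full(mz.shape, np.inf)
    for shift in (0, -1):
        j = np.clip(idx + shift, 0, len(theo) - 1)
        dist = np.minimum(dist, np.abs(theo[j] - mz))
    peak_matched = dist <= tolerance
    # theoretical fragment -> any confirming peak
    fidx = np.searchsorted(mz, theo)
    fdist = np.full(theo.shape, np.inf)
    for shift in (0, -1):
        j = np.clip(fidx + shift, 0, len(mz) - 1)
        fdist = np.minimum(fdist, np.abs(mz[j] - theo))
    n_match = int((fdist <= tolerance).sum())

    i_n = inten / max_i if max_i > 0 else inten
    denom = float(i_n.sum())
    vs = 100.0 * float(i_n[peak_matched].sum()) / denom if denom > 0 else 0.0

    spectral_range = float(mz.max() - mz.min()) if len(mz) > 1 else 2 * tolerance
    spectral_range = max(spectral_range, 2 * tolerance)
    p2 = p2_of(len(theoretical), tolerance, spectral_range)
    pp = pp_score(len(theoretical), n_match, p2)

    i_match_total = float(inten[peak_matched].sum())
    mu_1, sd_1 = float(inten.mean()), float(inten.std())
    k = max(int(peak_matched.sum()), 1)
    mu = k * mu_1
    sigma = max(math.sqrt(k) * sd_1, 1e-9)
    pp2 = pp2_score(i_match_total, mu, sigma)

    return MatchReport(
        bond=theoretical.pair.bond,
        vs_score=vs,
        pp=pp,
        pp2=pp2,
        precursor_mass=spectrum.precursor_mass,
        n_match=n_match,
        n_theoretical=len(theoretical),
    )


def score_spectrum(
    protein: Protein,
    spectrum: Spectrum,
    pairs: Sequence[DisulfidePair] | None = None,
    config: MSConfig | None = None,
    protease: Literal["trypsin", "chymotrypsin"] = "trypsin",
    missed_cleavages: int = 1,
) -> list[MatchReport]:
    """Score every candidate pair compatible with the spectrum's precursor."""
    config = config or MSConfig()
    if pairs is None:
        pairs = enumerate_pairs(protein, protease, missed_cleavages)
    candidates = filter_by_precursor(
        pairs, spectrum.precursor_mass, config.precursor_tolerance
    )
    reports = []
    for pair in candidates:
        theo = theoretical_fragments(pair)
        if len(theo) == 0:
            continue
        reports.append(
            match_score_vs(
                spectrum, theo, tolerance=config.tolerance,
                intensity_floor=config.intensity_floor,
            )
        )
    return reports


def global_topology(bond_scores: dict[BondHypothesis, float]) -> Topology:
    """Maximum-weight matching over the cysteine graph.

    Edges are inserted in sorted bond order so the result is deterministic;
    any co-optimal matching has the same total weight.
    """
    if any(s < 0 for s in bond_scores.values()):
        raise ValueError("bond scores must be non-negative")
    g = nx.Graph()
    for b in sorted(bond_scores):
        g.add_edge(b.cys_a, b.cys_b, weight=bond_scores[b])
    matching = nx.max_weight_matching(g)
    return Topology(frozenset(bond(a, b) for a, b in matching))


def read_mgf(path: str | os.PathLike) -> list[Spectrum]:
    """Read an MGF peak list; precursor m/z and charge give neutral mass."""
    spectra = []
    with pmgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params["pepmass"]
            mz0 = pepmass[0] if isinstance(pepmass, (tuple, list)) else float(pepmass)
            charge = int(params.get("charge", [1])[0])
            neutral = (mz0 - PROTON) * charge
            peaks = list(
                zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
            )
            spectra.append(
                Spectrum(
                    precursor_mass=neutral,
                    precursor_charge=charge,
                    peaks=peaks,
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | os.PathLike) -> None:
    entries = []
    for i, s in enumerate(spectra):
        mz_prec = s.precursor_mass / s.precursor_charge + PROTON
        entries.append(
            {
                "m/z array": np.array([p[0] for p in s.peaks]),
                "intensity array": np.array([p[1] for p in s.peaks]),
                "params": {
                    "title": s.title or f"spectrum_{i}",
                    "pepmass": mz_prec,
                    "charge": s.precursor_charge,
                },
            }
        )
    pmgf.write(entries, output=str(path), file_mode="w")
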