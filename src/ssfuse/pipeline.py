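"""End-to-end fusion: evidence sets -> frame -> masses -> fused bond scores.

This is the path the case-study analysis takes: build the frame of
discernment from the union of reported bonds, convert each method's
per-bond beliefs into a mass function with the subset-scoring assignment,
combine under the chosen rule, and read off per-bond containment-sum
beliefs.  Discount weights (used by the Shafer rule) can be given
explicitly or derived from evidence metadata via the discounting rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .combine import CombinationResult, DiscountWeights, Rule, bond_scores, combine
from .core import BondHypothesis, EvidenceSet
from .discounting import DiscountConfig, discount_csp, discount_ms, discount_svm
from .hypothesis import Frame, MassFunction, assign_masses, build_frame, enumerate_consistent_subsets


@dataclass
class FusionOutput:
    frame: Frame
    per_method_masses: dict[str, MassFunction]
    result: CombinationResult
    scores: dict[BondHypothesis, float]


def fuse_evidence(
    evidence_sets: Sequence[EvidenceSet],
    rule: Rule = "shafer",
    weights: Sequence[DiscountWeights] | Sequence[float] | None = None,
    mode: Literal["union", "all-pairs"] = "union",
    max_card: int = 4,
    cys_positions: Sequence[int] | None = None,
) -> FusionOutput:
    """Fuse one protein's evidence sets under a combination rule.

    ``weights`` (one per evidence set, in order) are only consumed by the
    Shafer rule; the product-based rules combine undiscounted masses.
    """
    frame = build_frame(list(evidence_sets), mode=mode, cys_positions=cys_positions)
    subsets = enumerate_consistent_subsets(frame, max_card=max_card)
    masses = {s.method: assign_masses(frame, s, subsets) for s in evidence_sets}
    result = combine(list(masses.values()), rule=rule, weights=weights)
    return FusionOutput(
        frame=frame,
        per_method_masses=masses,
        result=result,
        scores=bond_scores(result),
    )


def weights_from_metadata(
    evidence_sets: Sequence[EvidenceSet],
    metadata: Mapping[tuple[str, str, BondHypothesis], Mapping[str, float]],
    cfg: DiscountConfig | None = None,
) -> list[DiscountWeights]:
    """Derive one reliability weight per evidence set from its metadata.

    MS-style sources need ``precursor_mass`` and ``pp2`` columns, CSP
    sources ``divergence`` and ``n_best_matches``; SVM sources are
    discounted from their own belief.  Per-bond weights within a source
    are averaged into the source weight (the discount-and-average rule
    takes one alpha per source).  Sources without usable metadata keep
    weight 1.
    """
    cfg = cfg or DiscountConfig()
    out: list[DiscountWeights] = []
    for s in evidence_sets:
        per_bond: list[float] = []
        for ev in s.items:
            meta = metadata.get((s.protein_id, s.method, ev.bond), {})
            if "precursor_mass" in meta and "pp2" in meta:
                per_bond.append(
                    discount_ms(meta["precursor_mass"], meta["pp2"], cfg).alpha
                )
            elif "divergence" in meta:
                per_bond.append(
                    discount_csp(
                        meta["divergence"], int(meta.get("n_best_matches", 1))
                    ).alpha
                )
            elif s.method.upper().startswith("SVM"):
                per_bond.append(discount_svm(ev.belief).alpha)
        alpha = sum(per_bond) / len(per_bond) if per_bond else 1.0
        out.append(DiscountWeights(method=s.method, alpha=alpha))
    return out
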