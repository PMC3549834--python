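"""Per-source reliability weights for the discount-and-average rule.

Sources are not equally trustworthy, and their trustworthiness can be
judged from the data itself.  For MS evidence, large precursor ions
fragment poorly, so bonds confirmed on heavy precursors are de-rated; a
low pp2 score (the matched-abundance significance) signals weak spectral
support and is de-rated too.  SVM beliefs are taken at face value only
when very confident; mid- and low-confidence predictions are divided
down.  CSP transfers are penalised for large profile divergence and for
an unambiguous-match count below two.

All decrements are subtractive and weights are clamped to [0, 1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import yaml

from .combine import DiscountWeights

__all__ = [
    "DiscountConfig",
    "DiscountWeights",
    "discount_ms",
    "discount_svm",
    "discount_csp",
]


@dataclass(frozen=True)
class DiscountConfig:
    """Thresholds and decrements for the data-driven MS discounting.

    t_mass: precursor-mass threshold in Daltons above which fragmentation
        becomes unreliable (default 4000 Da).
    t_pp: pp2 threshold below which matched abundance looks random
        (default 50, on the -log10 scale).
    alpha_mass / alpha_pp: the corresponding subtractive decrements
        (defaults 0.1 and 0.2).
    """

    t_mass: float = 4000.0
    t_pp: float = 50.0
    alpha_mass: float = 0.1
    alpha_pp: float = 0.2

    def __post_init__(self) -> None:
        if self.t_mass <= 0 or self.t_pp <= 0:
            raise ValueError("thresholds must be positive")
        for name in ("alpha_mass", "alpha_pp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "DiscountConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _clamp(w: float) -> float:
    return min(1.0, max(0.0, w))


def discount_ms(
    precursor_mass: float, pp2: float, cfg: DiscountConfig | None = None
) -> DiscountWeights:
    """Reliability of one MS-confirmed bond.

    Starts at 1; loses ``alpha_mass`` if the precursor exceeds ``t_mass``
    Da, and ``alpha_pp`` if the pp2 score falls below ``t_pp``.
    """
    if precursor_mass <= 0:
        raise ValueError("precursor mass must be positive")
    cfg = cfg or DiscountConfig()
    w = 1.0
    if precursor_mass > cfg.t_mass:
        w -= cfg.alpha_mass
    if pp2 < cfg.t_pp:
        w -= cfg.alpha_pp
    return DiscountWeights(method="MS", alpha=_clamp(w))


def discount_svm(belief: float) -> DiscountWeights:
    """Reliability of an SVM prediction, derived from its own belief.

    The weight starts equal to the belief; beliefs in (0.5, 0.9) are
    divided by 1.5 and beliefs <= 0.5 by 3.  Boundary conventions: exactly
    0.9 keeps full weight, exactly 0.5 falls in the /3 branch.
    """
    if not 0.0 <= belief <= 1.0:
        raise ValueError(f"belief must lie in [0, 1], got {belief}")
    if belief >= 0.9:
        w = belief
    elif belief > 0.5:
        w = belief / 1.5
    else:
        w = belief / 3.0
    return DiscountWeights(method="SVM", alpha=_clamp(w))


def discount_csp(divergence: float, n_best_matches: int) -> DiscountWeights:
    """Reliability of a CSP topology transfer.

    Starts at 1; loses D/100 when the profile divergence D exceeds 10, and
    a further 0.1 when fewer than two reference entries share the minimal
    divergence.  D exactly 10 incurs no decrement.
    """
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    if n_best_matches < 0:
        raise ValueError("n_best_matches must be non-negative")
    w = 1.0
    if divergence > 10.0:
        w -= divergence / 100.0
    if n_best_matches < 2:
        w -= 0.1
    return DiscountWeights(method="CSP", alpha=_clamp(w))
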