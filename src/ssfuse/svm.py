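"""Sequence-window SVM prediction of disulfide bonds.

Each candidate cysteine pair is encoded by the local sequence environment
of its two cysteines: a 13-residue window centred on each cysteine (6 on
either side), every window position one-hot over the 20 standard amino
acids, plus the raw residue separation d_ss between the two cysteines —
2 x 13 x 20 + 1 = 521 features.  Window positions falling outside the
sequence, and non-standard residues (X, U, B, Z, ...), encode as all-zero
blocks.

The classifier itself is pluggable: anything that maps a feature matrix to
real margins (positive = bonded) works.  Margins are calibrated into
beliefs with a sigmoid

    sigma_SVM = 1 / (1 + exp(A f + B)),

whose parameters are fitted by regularised maximum likelihood on held-out
margins (Platt scaling with the standard smoothed targets).  A small
reference trainer around scikit-learn's RBF SVC is provided for synthetic
and fixture data; it is not a substitute for a production model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import BondHypothesis, Evidence, EvidenceSet, Protein

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

WINDOW = 13
HALF_WINDOW = WINDOW // 2
N_FEATURES = 2 * WINDOW * len(AMINO_ACIDS) + 1  # 521

#: A margin scorer: (n_pairs, 521) feature matrix -> (n_pairs,) real margins.
MarginClassifier = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class PlattParams:
    """Sigmoid calibration parameters; A < 0 makes belief increase with
    the margin (positive margin = bonded)."""

    A: float
    B: float


def _window_block(sequence: str, center: int) -> np.ndarray:
    """One-hot encode the 13-residue window centred on 1-based ``center``."""
    block = np.zeros((WINDOW, len(AMINO_ACIDS)))
    for w, pos in enumerate(range(center - HALF_WINDOW, center + HALF_WINDOW + 1)):
        if 1 <= pos <= len(sequence):
            idx = _AA_INDEX.get(sequence[pos - 1].upper())
            if idx is not None:
                block[w, idx] = 1.0
    return block.ravel()


def encode_pair(protein: Protein, b: BondHypothesis) -> np.ndarray:
    """521-feature descriptor for a candidate bond of ``protein``."""
    for pos in (b.cys_a, b.cys_b):
        if pos not in protein.cys_positions:
            raise ValueError(
                f"{protein.id}: position {pos} is not a cysteine of this protein"
            )
    features = np.concatenate(
        [
            _window_block(protein.sequence, b.cys_a),
            _window_block(protein.sequence, b.cys_b),
            [float(b.cys_b - b.cys_a)],
        ]
    )
    assert features.shape == (N_FEATURES,)
    return features


def platt_belief(f: float, params: PlattParams) -> float:
    """Calibrated belief 1/(1 + exp(A f + B)), strictly inside (0, 1)."""
    z = params.A * f + params.B
    if z >= 0:
        p = float(math.exp(-z) / (1.0 + math.exp(-z)))
    else:
        p = float(1.0 / (1.0 + math.exp(z)))
    # keep the open interval even where the sigmoid saturates in floats
    return min(max(p, 1e-300), 1.0 - 1e-16)


def fit_platt(
    margins: Sequence[float],
    labels: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> PlattParams:
    """Fit (A, B) by regularised maximum likelihood (Platt scaling).

    Targets are the usual smoothed frequencies t+ = (N+ + 1)/(N+ + 2) and
    t- = 1/(N- + 2), which regularise the fit away from 0/1; optimisation
    is Newton's method with backtracking on the cross-entropy.
    """
    f = np.asarray(margins, dtype=float)
    y = np.asarray(labels, dtype=int)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("margins and labels must be equal-length 1-D sequences")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are required to fit the calibration")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(a: float, b: float) -> float:
        z = a * f + b
        # cross-entropy of p = 1/(1+e^z) against targets t, stably
        return float(np.sum(t * np.logaddexp(0.0, z) + (1 - t) * np.logaddexp(0.0, -z)))

    a, b = 0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))
    obj = objective(a, b)
    for _ in range(max_iter):
        z = a * f + b
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        # d(obj)/dz = t*s(z) + (1-t)*(s(z)-1) = s(z) - (1-t)... with p = s(-z):
        g = (1.0 - p) - (1.0 - t)  # gradient of obj wrt z per sample
        grad = np.array([np.sum(g * f), np.sum(g)])
        w = np.maximum(p * (1.0 - p), 1e-12)
        h11 = np.sum(w * f * f) + 1e-12
        h12 = np.sum(w * f)
        h22 = np.sum(w) + 1e-12
        det = h11 * h22 - h12 * h12
        if det <= 0:
            break
        da = -(h22 * grad[0] - h12 * grad[1]) / det
        db = -(h11 * grad[1] - h12 * grad[0]) / det
        step = 1.0
        while step >= 1e-10:
            new_obj = objective(a + step * da, b + step * db)
            if new_obj < obj + 1e-12:
                break
            step /= 2.0
        a, b = a + step * da, b + step * db
        if abs(obj - new_obj) < tol:
            obj = new_obj
            break
        obj = new_obj
    return PlattParams(A=a, B=b)


def predict_pairs(
    protein: Protein,
    classifier: MarginClassifier,
    params: PlattParams,
    belief_floor: float = 0.0,
) -> EvidenceSet:
    """Score every cysteine pair of ``protein`` and calibrate to beliefs.

    Pairs whose calibrated belief falls below ``belief_floor`` are
    omitted.  Proteins with fewer than two cysteines yield an empty set.
    """
    pairs = protein.all_pairs()
    if not pairs:
        return EvidenceSet(protein_id=protein.id, method="SVM", items=[])
    features = np.vstack([encode_pair(protein, b) for b in pairs])
    margins = np.asarray(classifier(features), dtype=float).ravel()
    if margins.shape != (len(pairs),):
        raise ValueError("classifier must return one margin per pair")
    items = []
    for b, f in zip(pairs, margins):
        belief = platt_belief(float(f), params)
        if belief >= belief_floor:
            items.append(Evidence(bond=b, belief=belief, method="SVM"))
    return EvidenceSet(protein_id=protein.id, method="SVM", items=items)


def train_reference_classifier(
    features: np.ndarray,
    labels: Sequence[int],
    C: float = 1.0,
    gamma: str | float = "scale",
    random_state: int = 0,
) -> MarginClassifier:
    """Train a small RBF-SVC margin scorer on encoded pairs.

    Intended for synthetic and fixture data; returns a callable mapping a
    feature matrix to decision-function margins.
    """
    from sklearn.svm import SVC

    model = SVC(kernel="rbf", C=C, gamma=gamma, random_state=random_state)
    model.fit(np.asarray(features, dtype=float), np.asarray(labels, dtype=int))
    return model.decision_function
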