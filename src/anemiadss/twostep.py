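"""Two-step ternary classification with an ROC-selected operating point.

Picking the argmax of (P_UP, P_STAY, P_DOWN) under-calls dose changes: the
timing of UP and DOWN matters more than overall agreement, so the STAY
decision gets its own operating point.  Step one: the direction is STAY if
P_STAY exceeds a threshold T (strictly — at T=1 a STAY is never emitted).
Step two: otherwise whichever of UP/DOWN has the larger probability (for
the binary iron model, step two is always UP).

T is chosen from the ROC curve of the STAY-vs-NON-STAY binary problem
(NON-STAY positive) as the point nearest (FPR, TPR) = (0, 1); ties break
toward the larger T, i.e. toward calling more dose changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import Direction, Medication

logger = logging.getLogger(__name__)

__all__ = ["Threshold", "RocCurve", "classify", "classify_all", "roc_curve",
           "select_threshold"]

DEFAULT_GRID_SIZE = 201
# operating points learned from the original hospital training records,
# shipped as reference defaults for use without retraining
REFERENCE_THRESHOLDS = {Medication.ESA: 0.475, Medication.IS: 0.470}


@dataclass(frozen=True)
class Threshold:
    t: float
    medication: Medication = Medication.ESA

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= 1.0):
            raise ValueError(f"threshold must be in [0, 1], got {self.t}")


@dataclass(frozen=True)
class RocCurve:
    """Operating characteristic of the STAY-vs-NON-STAY split as the
    threshold sweeps [0, 1].  Points are (t, FPR, TPR), FPR/TPR
    non-decreasing in t; AUC by the trapezoidal rule."""

    points: tuple[tuple[float, float, float], ...]
    auc: float

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p[2] for p in self.points])


def _stay_index(classes: Sequence[str]) -> int:
    return list(classes).index("STAY")


def classify(probs, thr: Threshold, classes: Sequence[str] = ("UP", "STAY", "DOWN")):
    """Two-step rule for one occasion.

    ``probs`` is a sequence of probabilities in ``classes`` order.  STAY iff
    P_STAY > t; otherwise the larger of UP/DOWN (an exact tie goes to UP —
    under-treated anemia being the flagged clinical risk)."""
    classes = tuple(classes)
    p = np.asarray(probs, dtype=float)
    if p.shape != (len(classes),):
        raise ValueError("probability vector does not match classes")
    if p[_stay_index(classes)] > thr.t:
        return Direction.STAY
    if "DOWN" not in classes:
        return Direction.UP
    p_up, p_down = p[classes.index("UP")], p[classes.index("DOWN")]
    if p_up == p_down:
        logger.info("exact UP/DOWN probability tie at %.6f: resolved to UP", p_up)
    return Direction.UP if p_up >= p_down else Direction.DOWN


def classify_all(probs: np.ndarray, thr: Threshold,
                 classes: Sequence[str] = ("UP", "STAY", "DOWN")) -> np.ndarray:
    """Vectorized two-step rule; returns an integer array of class indices
    into ``classes``."""
    classes = tuple(classes)
    s = _stay_index(classes)
    stay = probs[:, s] > thr.t
    out = np.empty(len(probs), dtype=np.int64)
    out[stay] = s
    if "DOWN" in classes:
        u, d = classes.index("UP"), classes.index("DOWN")
        non = ~stay
        ties = int((probs[non, u] == probs[non, d]).sum())
        if ties:
            logger.info("%d exact UP/DOWN probability ties resolved to UP", ties)
        out[non] = np.where(probs[non, u] >= probs[non, d], u, d)
    else:
        out[~stay] = classes.index("UP")
    return out


def roc_curve(
    probs: np.ndarray,
    labels: np.ndarray,
    classes: Sequence[str] = ("UP", "STAY", "DOWN"),
    grid: Optional[np.ndarray] = None,
) -> RocCurve:
    """ROC of the first classification step.

    Positives are true NON-STAY occasions; an occasion is *called*
    NON-STAY when P_STAY <= t.  With ``grid=None`` the curve steps through
    every distinct P_STAY value (so the trapezoidal AUC equals the
    pairwise-concordance estimator exactly); a fixed grid, e.g. 201 evenly
    spaced thresholds, matches how the operating point is searched.
    """
    classes = tuple(classes)
    s = _stay_index(classes)
    p_stay = np.asarray(probs[:, s], dtype=float)
    pos = np.asarray(labels) != s          # true NON-STAY
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: labels contain a single class")
    if grid is None:
        ts = np.unique(np.concatenate([[0.0], np.unique(p_stay), [1.0]]))
    else:
        ts = np.asarray(grid, dtype=float)
    # called NON-STAY iff p_stay <= t
    called = p_stay[None, :] <= ts[:, None]
    tpr = (called & pos[None, :]).sum(axis=1) / n_pos
    fpr = (called & ~pos[None, :]).sum(axis=1) / n_neg
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    points = tuple((float(t), float(f), float(r)) for t, f, r in zip(ts, fpr, tpr))
    return RocCurve(points=points, auc=auc)


def default_grid(size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    return np.linspace(0.0, 1.0, size)


def select_threshold(roc: RocCurve, medication: Medication = Medication.ESA) -> Threshold:
    """The threshold whose ROC point is nearest (0, 1): it balances the
    ability to call STAY and NON-STAY.  Ties break toward larger t (more
    dose changes, favouring timing sensitivity)."""
    d = np.sqrt(roc.fpr ** 2 + (1.0 - roc.tpr) ** 2)
    ts = roc.thresholds
    best = np.flatnonzero(d == d.min())
    idx = best[np.argmax(ts[best])]
    return Threshold(t=float(ts[idx]), medication=medication)
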