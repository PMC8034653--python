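"""ROC curves for discriminating unpaired from paired residues by
mutation frequency.

Ground truth comes from a reference structure: unpaired bases are
positives, internally-paired bases negatives, and terminally-paired
bases (helix ends and isolated pairs) are excluded — a terminal pair's
flexibility is ambiguous, so it would pollute both classes.  When an
accessibility mask is given (in vivo evaluation), bases outside it are
excluded too.  The threshold sweeps a linear grid over [0, 1] (default
step 0.001); at each threshold a base counts as called when its
frequency strictly exceeds the threshold.  AUC is the trapezoidal area
over the swept points augmented with (0,0) and (1,1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats import ReferenceStructure
from .structure_stats import INTERNAL, UNPAIRED, classify_pairing_state

logger = logging.getLogger(__name__)

__all__ = ["RocCurve", "label_bases", "roc_curve", "auc_compare",
           "POSITIVE", "NEGATIVE", "EXCLUDED"]

POSITIVE, NEGATIVE, EXCLUDED = 1, 0, -1


def label_bases(structure: ReferenceStructure,
                accessibility_mask: set[int] | None = None) -> np.ndarray:
    """Per-base ROC labels, 1-based in a length n+1 array (entry 0 unused).

    Unpaired -> positive, internally-paired -> negative, terminally-paired
    -> excluded; with a mask (1-based transcript positions), any base
    absent from it is excluded.
    """
    states = classify_pairing_state(structure)
    labels = np.full(structure.n + 1, EXCLUDED, dtype=np.int8)
    labels[1:][states[1:] == UNPAIRED] = POSITIVE
    labels[1:][states[1:] == INTERNAL] = NEGATIVE
    if accessibility_mask is not None:
        for i in range(1, structure.n + 1):
            if i not in accessibility_mask:
                labels[i] = EXCLUDED
    return labels


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int
    eval_positions: np.ndarray | None = None
    _pos_values: np.ndarray | None = None
    _neg_values: np.ndarray | None = None


def roc_curve(frequencies, labels, step: float = 0.001,
              positions=None) -> RocCurve:
    """Sweep the frequency threshold from 1 down to 0 on a linear grid.

    ``frequencies`` and ``labels`` are aligned arrays (labels use the
    POSITIVE/NEGATIVE/EXCLUDED codes); bases that are excluded or have an
    undefined (NaN) frequency are dropped before the sweep.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    labels = np.asarray(labels)
    if frequencies.shape != labels.shape:
        raise ValueError("frequencies and labels must be aligned")
    keep = (labels != EXCLUDED) & ~np.isnan(frequencies)
    pos = np.sort(frequencies[keep & (labels == POSITIVE)])
    neg = np.sort(frequencies[keep & (labels == NEGATIVE)])
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"need at least one positive and one negative evaluated base "
            f"(got {pos.size} positives, {neg.size} negatives)")
    thresholds = np.arange(0.0, 1.0 + step / 2, step)[::-1]
    # strict '>': count of values exceeding t via searchsorted on sorted arrays
    tpr = (pos.size - np.searchsorted(pos, thresholds, side="right")) / pos.size
    fpr = (neg.size - np.searchsorted(neg, thresholds, side="right")) / neg.size
    xs = np.concatenate([[0.0], fpr, [1.0]])
    ys = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(ys, xs))
    eval_pos = None
    if positions is not None:
        eval_pos = np.asarray(positions)[keep]
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
                    n_positive=int(pos.size), n_negative=int(neg.size),
                    eval_positions=eval_pos, _pos_values=pos, _neg_values=neg)


def roc_from_structure(frequencies, structure: ReferenceStructure,
                       accessibility_mask: set[int] | None = None,
                       step: float = 0.001) -> RocCurve:
    """Convenience wrapper: label from the structure, then sweep.

    ``frequencies`` is a length-n array aligned with the sequence
    (position i at index i-1)."""
    labels = label_bases(structure, accessibility_mask)[1:]
    positions = np.arange(1, structure.n + 1)
    return roc_curve(np.asarray(frequencies, float), labels, step=step,
                     positions=positions)


@dataclass
class AucDelta:
    delta: float
    auc_a: float
    auc_b: float
    n_overlap: int | None = None


def auc_compare(curve_a: RocCurve, curve_b: RocCurve) -> AucDelta:
    """AUC difference (a minus b) for curves built on the same bases.

    If both curves carry evaluated-position sets and they differ, a
    warning is logged and the overlap size reported; the AUC delta is
    still returned on each curve's own base set.
    """
    n_overlap = None
    a_pos, b_pos = curve_a.eval_positions, curve_b.eval_positions
    if a_pos is not None and b_pos is not None:
        sa, sb = set(a_pos.tolist()), set(b_pos.tolist())
        n_overlap = len(sa & sb)
        if sa != sb:
            logger.warning(
                "auc_compare: curves evaluate different base sets "
                "(%d vs %d bases, %d shared)", len(sa), len(sb), n_overlap)
    return AucDelta(delta=curve_a.auc - curve_b.auc, auc_a=curve_a.auc,
                    auc_b=curve_b.auc, n_overlap=n_overlap)
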