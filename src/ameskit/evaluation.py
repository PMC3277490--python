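"""ROC construction, AUC, vertical averaging and sensitivity cutoffs.

The trapezoidal AUC here is, by construction, the Mann-Whitney
concordance (#concordant pairs + half ties) / (n+ * n-); a brute-force
pair count is used as the independent check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

DEFAULT_FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class RocCurve:
    """Ordered (fpr, tpr) points from (0,0) to (1,1).

    ``higher_is_positive`` records the declared score orientation: the
    curve is built by thresholding ``score >= t`` after flipping the sign
    when the orientation says low scores indicate positives (it is a
    declaration, never auto-flipped to force AUC >= 0.5).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray = field(default=None, repr=False)
    higher_is_positive: bool = True


def roc_curve(scores, labels, higher_is_positive: bool = True) -> RocCurve:
    """ROC with thresholds swept over unique scores; tied scores move
    together, producing diagonal segments."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    oriented = scores if higher_is_positive else -scores
    fpr, tpr, thr = _skm.roc_curve(labels, oriented, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, higher_is_positive=higher_is_positive)


def auc(curve_or_scores, labels=None, higher_is_positive: bool = True) -> float:
    """Trapezoidal area under a RocCurve (or directly from scores)."""
    if isinstance(curve_or_scores, RocCurve):
        c = curve_or_scores
    else:
        c = roc_curve(curve_or_scores, labels, higher_is_positive)
    return float(np.trapezoid(c.tpr, c.fpr))


def concordance_auc(scores, labels, higher_is_positive: bool = True) -> float:
    """Brute-force Mann-Whitney concordance over all pos-neg pairs;
    independent of the trapezoid path (used as an oracle)."""
    scores = np.asarray(scores, dtype=float)
    if not higher_is_positive:
        scores = -scores
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


@dataclass
class AveragedRoc:
    """Vertically averaged ROC: mean and sample SD of tpr on a fixed fpr
    grid."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray
    n_curves: int


def _tpr_at(curve: RocCurve, grid: np.ndarray) -> np.ndarray:
    # Collapse vertical segments (repeated fpr) to their upper tpr, then
    # interpolate linearly: the conventional vertical-averaging reading.
    fpr, tpr = curve.fpr, curve.tpr
    uniq, idx = np.unique(fpr, return_index=True)
    upper = np.maximum.reduceat(tpr, idx)
    # tpr is non-decreasing, so the max over each fpr block is its last value
    return np.interp(grid, uniq, upper)


def vertical_average(curves, grid=None) -> AveragedRoc:
    """Mean +/- sample SD of tpr at each grid fpr across curves."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    grid = DEFAULT_FPR_GRID if grid is None else np.asarray(grid, dtype=float)
    tprs = np.vstack([_tpr_at(c, grid) for c in curves])
    sd = tprs.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(len(grid))
    return AveragedRoc(
        fpr_grid=grid,
        mean_tpr=tprs.mean(axis=0),
        sd_tpr=sd,
        n_curves=len(curves),
    )


def sensitivity_cutoff(scores, labels, target_sensitivity: float = 0.80,
                       higher_is_positive: bool = True) -> float:
    """Smallest threshold movement achieving at least the target
    sensitivity on the given data.

    Classification is ``score >= cutoff`` (after orientation).  A target
    of 0 is a degenerate request; the policy is to return the most
    conservative useful threshold, i.e. one admitting the single
    top-scoring positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not higher_is_positive:
        scores = -scores
    pos = np.sort(scores[labels == 1])[::-1]
    if len(pos) == 0:
        raise ValueError("no positives")
    k = max(1, int(np.ceil(target_sensitivity * len(pos))))
    cutoff = pos[k - 1]
    return cutoff if higher_is_positive else -cutoff
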