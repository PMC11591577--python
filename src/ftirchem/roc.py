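"""Single-wavenumber diagnostic evaluation.

ROC curve over midpoint cut values, rank-based (Mann-Whitney) AUC with a
p-value, and the Youden-index optimal cut point.  Because band maxima
appear as negative minima in second-derivative spectra, the clinically
relevant decision rule is often "positive if the value is <= cut"; the
direction is explicit in every result and can be auto-chosen as the
orientation with AUC >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

__all__ = ["RocResult", "roc_curve", "auc_mann_whitney", "youden_cut"]

POSITIVE_IF_LOW = "positive-if-low"
POSITIVE_IF_HIGH = "positive-if-high"

#: Exact Mann-Whitney enumeration is used up to this many positive*negative pairs.
EXACT_PAIR_LIMIT = 400


@dataclass
class RocResult:
    cuts: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    p_value: float
    direction: str
    youden_cut: float
    youden_sens: float
    youden_spec: float
    youden_j: float

    @property
    def rule(self) -> str:
        op = "<=" if self.direction == POSITIVE_IF_LOW else ">="
        return f"positive if value {op} {self.youden_cut:g}"


def _check_binary(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return values, labels


def auc_mann_whitney(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC = U/(n1*n2) with ties counted one half, plus a two-sided p-value.

    The p-value comes from exact enumeration of the U statistic when
    n1*n2 <= 400 and there are no ties, otherwise from the tie-corrected
    normal approximation.  Orientation: AUC > 0.5 means positives score
    HIGH.
    """
    values, labels = _check_binary(values, labels)
    pos, neg = values[labels], values[~labels]
    n1, n2 = pos.size, neg.size
    ranks = rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)
    has_ties = np.unique(values).size < values.size
    method = "exact" if (n1 * n2 <= EXACT_PAIR_LIMIT and not has_ties) else "asymptotic"
    res = mannwhitneyu(pos, neg, alternative="two-sided", method=method,
                       use_continuity=False)
    return float(auc), float(res.pvalue)


def roc_curve(values: np.ndarray, labels: np.ndarray,
              direction: str | None = None) -> RocResult:
    """Full sensitivity/specificity sweep over midpoint cut values.

    ``labels`` is boolean (True = positive class).  Cut values sit at the
    midpoints of adjacent sorted unique values, padded with -inf/+inf so
    the all-positive and all-negative rules are included.  If ``direction``
    is None, the orientation giving AUC >= 0.5 is chosen and reported.
    """
    values, labels = _check_binary(values, labels)
    auc_high, p = auc_mann_whitney(values, labels)
    if direction is None:
        direction = POSITIVE_IF_HIGH if auc_high >= 0.5 else POSITIVE_IF_LOW
    elif direction not in (POSITIVE_IF_LOW, POSITIVE_IF_HIGH):
        raise ValueError(f"unknown direction {direction!r}")
    auc = auc_high if direction == POSITIVE_IF_HIGH else 1.0 - auc_high

    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    cuts = np.concatenate([[-np.inf], mids, [np.inf]])
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if direction == POSITIVE_IF_LOW:
        called_pos = values[None, :] <= cuts[:, None]
    else:
        called_pos = values[None, :] >= cuts[:, None]
    sens = (called_pos & labels).sum(axis=1) / n_pos
    spec = ((~called_pos) & ~labels).sum(axis=1) / n_neg

    cut, s, sp, j = _youden(cuts, sens, spec)
    return RocResult(cuts=cuts, sensitivity=sens, specificity=spec, auc=auc,
                     p_value=p, direction=direction, youden_cut=cut,
                     youden_sens=s, youden_spec=sp, youden_j=j)


def _youden(cuts: np.ndarray, sens: np.ndarray,
            spec: np.ndarray) -> tuple[float, float, float, float]:
    j = sens + spec - 1.0
    best = j.max()
    tied = np.flatnonzero(np.isclose(j, best, rtol=0, atol=1e-12))
    # ties: prefer higher sensitivity, then the lower cut value
    tied = tied[sens[tied] == sens[tied].max()]
    i = tied[np.argmin(cuts[tied])]
    return float(cuts[i]), float(sens[i]), float(spec[i]), float(j[i])


def youden_cut(r: RocResult) -> tuple[float, float, float, float]:
    """(cut, sensitivity, specificity, J) maximizing sens + spec - 1."""
    return _youden(r.cuts, r.sensitivity, r.specificity)
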