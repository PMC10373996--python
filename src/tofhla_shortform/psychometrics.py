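"""Validation statistics for a short form against the full-length score.

Internal consistency (Cronbach's alpha), item-to-scale point-biserial
correlations with strength bands, Pearson correlation with a Fisher-z 95%
confidence interval, and ordinal classification analytics (3x3 confusion
matrix, one-vs-rest accuracies, off-by-k counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .items import ResponseMatrix, ScoreVector
from .scoring import Level

__all__ = [
    "AlphaResult",
    "ItemScaleCorrelation",
    "ConfusionMatrix3",
    "PsychometricsError",
    "cronbach_alpha",
    "point_biserial_all",
    "pearson_with_ci",
    "confusion",
    "one_vs_rest_accuracy",
    "off_by_k",
]

LEVEL_ORDER = (Level.INADEQUATE, Level.MARGINAL, Level.ADEQUATE)


class PsychometricsError(ValueError):
    pass


@dataclass(frozen=True)
class AlphaResult:
    """Cronbach's alpha and the conventional alpha > 0.7 reliability flag."""

    alpha: float
    n_items: int

    @property
    def reliable(self) -> bool:
        return self.alpha > 0.7


@dataclass(frozen=True)
class ItemScaleCorrelation:
    """Point-biserial correlation of one binary item with the total score.

    ``strength`` bands on |r|: weak [0, 0.2), medium [0.2, 0.5), high [0.5, 1]
    (lower bound inclusive). A constant item has no defined correlation and is
    flagged ``undefined`` rather than dropped.
    """

    item_id: str
    r_pb: float
    p_value: float
    undefined: bool = False

    @property
    def strength(self) -> str | None:
        if self.undefined:
            return None
        a = abs(self.r_pb)
        if a < 0.2:
            return "weak"
        if a < 0.5:
            return "medium"
        return "high"


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 level confusion matrix; rows = true, columns = predicted.

    Row/column order is fixed: inadequate, marginal, adequate.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (3, 3) or (c < 0).any():
            raise PsychometricsError("confusion matrix must be 3x3 non-negative counts")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))


def cronbach_alpha(responses: ResponseMatrix) -> AlphaResult:
    """Cronbach's alpha over the matrix's items.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance(item sum))`` with
    unbiased (n-1) sample variances.

    Raises if fewer than two items or participants, or if the total score has
    zero variance (alpha undefined).
    """
    X = responses.values.astype(float)
    n, k = X.shape
    if k < 2:
        raise PsychometricsError("Cronbach's alpha needs at least 2 items")
    if n < 2:
        raise PsychometricsError("Cronbach's alpha needs at least 2 participants")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise PsychometricsError("total score has zero variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1 - item_var / total_var)
    return AlphaResult(alpha=float(alpha), n_items=k)


def point_biserial_all(
    responses: ResponseMatrix, total_scores: ScoreVector
) -> list[ItemScaleCorrelation]:
    """Point-biserial correlation of every item with the total score.

    The point-biserial coefficient is the Pearson correlation between the
    binary item and the continuous score; p-values are two-sided.
    """
    if responses.participant_ids != total_scores.participant_ids:
        raise PsychometricsError("responses and scores cover different participants")
    y = total_scores.scores
    out = []
    for j, item_id in enumerate(responses.item_ids):
        x = responses.values[:, j].astype(float)
        if x.min() == x.max() or y.min() == y.max():
            out.append(ItemScaleCorrelation(item_id, math.nan, math.nan, undefined=True))
            continue
        res = stats.pearsonr(x, y)
        out.append(ItemScaleCorrelation(item_id, float(res.statistic), float(res.pvalue)))
    return out


def pearson_with_ci(
    x: ScoreVector | Sequence[float], y: ScoreVector | Sequence[float]
) -> tuple[float, tuple[float, float], float]:
    """Pearson r with a Fisher-z 95% CI and two-sided t-test p-value.

    The CI transforms r to ``z = atanh(r)``, takes ``z +/- 1.96/sqrt(n-3)``
    and maps back with tanh.
    """
    xv = np.asarray(x.scores if isinstance(x, ScoreVector) else x, dtype=float)
    yv = np.asarray(y.scores if isinstance(y, ScoreVector) else y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise PsychometricsError("inputs must be equal-length vectors")
    n = len(xv)
    if n < 4:
        raise PsychometricsError("need at least 4 observations for a CI")
    if xv.min() == xv.max() or yv.min() == yv.max():
        raise PsychometricsError("correlation undefined for a constant input")
    res = stats.pearsonr(xv, yv)
    r = float(res.statistic)
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        z = math.atanh(r)
        half = 1.96 / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    return r, ci, float(res.pvalue)


def _as_levels(levels: Sequence[Level | str]) -> list[Level]:
    out = []
    for lv in levels:
        try:
            out.append(Level(lv))
        except ValueError:
            raise PsychometricsError(f"unknown level value {lv!r}") from None
    return out


def confusion(
    true_levels: Sequence[Level | str], predicted_levels: Sequence[Level | str]
) -> ConfusionMatrix3:
    """Count (true, predicted) level pairs into the fixed-order 3x3 matrix."""
    t = _as_levels(true_levels)
    p = _as_levels(predicted_levels)
    if len(t) != len(p):
        raise PsychometricsError("true and predicted level vectors differ in length")
    counts = np.zeros((3, 3), dtype=int)
    for a, b in zip(t, p):
        counts[a.code, b.code] += 1
    return ConfusionMatrix3(counts)


def one_vs_rest_accuracy(m: ConfusionMatrix3, level: Level | str) -> int:
    """Binary accuracy of detecting ``level`` against the two other levels.

    Collapses the matrix to level-vs-rest and returns (TP + TN) / N as a
    whole percent, rounded half-up.
    """
    lv = Level(level)
    if m.n == 0:
        raise PsychometricsError("empty confusion matrix")
    i = lv.code
    tp = m.counts[i, i]
    tn = m.n - m.counts[i, :].sum() - m.counts[:, i].sum() + tp
    return int(math.floor((tp + tn) / m.n * 100 + 0.5))


def off_by_k(m: ConfusionMatrix3) -> dict[int, int]:
    """Counts of predictions exactly k ordinal levels away from truth, k in {0,1,2}."""
    out = {0: 0, 1: 0, 2: 0}
    for i in range(3):
        for j in range(3):
            out[abs(i - j)] += int(m.counts[i, j])
    return out
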