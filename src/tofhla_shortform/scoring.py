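"""Deterministic scorers for the full-length instrument and its short forms.

All scorers map a binary response matrix to per-participant points on the
instrument's 0-100 scale:

* :func:`score_full` — the full-length total score (reading and numeracy
  parts each worth 50 points, numeracy prorated).
* :func:`score_shortform` — an integer-weighted linear rule
  ``Y = b0 + sum(b_j * C_j)`` (the product of the exhaustive search).
* :func:`score_mirror_s` / :func:`score_mirror_prose` — the fixed-weight
  mirrors of the American short form: 2 points per reading item R1..R36 and
  7 points per numeracy item N1, N4, N5, N8 (the prose mirror drops numeracy).
* :func:`classify_level` — the ordinal inadequate / marginal / adequate
  classification.
* :func:`admin_time` — maximum administration time prorated per part and
  rounded up to whole minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .items import ItemBank, LevelScale, ResponseMatrix, ScoreVector, ShortFormModel

__all__ = [
    "Level",
    "AdminTimeModel",
    "ScoringError",
    "score_full",
    "score_shortform",
    "score_mirror_s",
    "score_mirror_prose",
    "classify_level",
    "classify_levels",
    "admin_time",
    "MIRROR_S_READING",
    "MIRROR_S_NUMERACY",
]


class ScoringError(ValueError):
    pass


class Level(str, Enum):
    """Ordinal health-literacy level; ordinal codes 0/1/2."""

    INADEQUATE = "inadequate"
    MARGINAL = "marginal"
    ADEQUATE = "adequate"

    @property
    def code(self) -> int:
        return ("inadequate", "marginal", "adequate").index(self.value)


# the American short form uses the first 36 reading items and numeracy 1, 4, 5, 8
MIRROR_S_READING = tuple(f"R{i}" for i in range(1, 37))
MIRROR_S_NUMERACY = ("N1", "N4", "N5", "N8")


@dataclass(frozen=True)
class AdminTimeModel:
    """Maximum administration time of the full instrument, per part, in minutes."""

    reading_minutes_full: int = 12
    numeracy_minutes_full: int = 10
    n_reading_full: int = 50
    n_numeracy_full: int = 17

    def __post_init__(self) -> None:
        if min(
            self.reading_minutes_full,
            self.numeracy_minutes_full,
            self.n_reading_full,
            self.n_numeracy_full,
        ) <= 0:
            raise ScoringError("administration-time parameters must be positive")


def _require_items(responses: ResponseMatrix, needed: list[str], what: str) -> None:
    missing = [i for i in needed if i not in responses.item_ids]
    if missing:
        raise ScoringError(f"{what}: responses are missing items {missing}")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def score_full(responses: ResponseMatrix, bank: ItemBank) -> ScoreVector:
    """Full-length total score on the 0-100 scale.

    Each part present in the bank contributes an equal share of the scale
    (50 points each when both parts exist): the raw number-correct in a part
    is prorated by ``share / n_items_in_part`` and the total is rounded
    half-up to an integer. For the canonical 67-item bank this is the usual
    rule — one point per reading item plus numeracy count x 50/17.
    """
    reading = [it.item_id for it in bank.reading_items]
    numeracy = [it.item_id for it in bank.numeracy_items]
    if not reading and not numeracy:
        raise ScoringError("bank has no items")
    _require_items(responses, reading + numeracy, "full-length score")
    total = np.zeros(responses.n_participants)
    share = 100.0 if not reading or not numeracy else 50.0
    if reading:
        total = total + responses.submatrix(reading).sum(axis=1) * (share / len(reading))
    if numeracy:
        total = total + responses.submatrix(numeracy).sum(axis=1) * (share / len(numeracy))
    return ScoreVector(responses.participant_ids, _round_half_up(total))


def score_shortform(responses: ResponseMatrix, model: ShortFormModel) -> ScoreVector:
    """Predicted total score under an integer-weighted short form.

    ``Y_i = intercept + sum_j weight_j * response_ij``, clipped to
    ``[0, score_max]`` so downstream level classification is always defined.
    """
    _require_items(responses, model.item_ids, "short-form score")
    if model.n_items:
        X = responses.submatrix(model.item_ids)
        w = np.array([model.weights[i] for i in model.item_ids], dtype=float)
        y = model.intercept + X @ w
    else:
        y = np.full(responses.n_participants, float(model.intercept))
    return ScoreVector(responses.participant_ids, np.clip(y, 0, model.scale.score_max))


def _fixed_weight_score(
    responses: ResponseMatrix, reading_ids: tuple[str, ...], numeracy_ids: tuple[str, ...]
) -> ScoreVector:
    needed = list(reading_ids) + list(numeracy_ids)
    _require_items(responses, needed, "fixed-weight mirror score")
    y = 2.0 * responses.submatrix(list(reading_ids)).sum(axis=1)
    if numeracy_ids:
        y = y + 7.0 * responses.submatrix(list(numeracy_ids)).sum(axis=1)
    return ScoreVector(responses.participant_ids, y)


def _require_bank_items(bank: ItemBank, needed: tuple[str, ...], what: str) -> None:
    missing = [i for i in needed if i not in set(bank.item_ids)]
    if missing:
        raise ScoringError(f"{what}: bank is missing items {missing}")


def score_mirror_s(responses: ResponseMatrix, bank: ItemBank) -> ScoreVector:
    """Mirror of the American short form: 2 x (R1..R36) + 7 x (N1,N4,N5,N8), max 100."""
    _require_bank_items(bank, MIRROR_S_READING + MIRROR_S_NUMERACY, "mirror score")
    return _fixed_weight_score(responses, MIRROR_S_READING, MIRROR_S_NUMERACY)


def score_mirror_prose(responses: ResponseMatrix, bank: ItemBank) -> ScoreVector:
    """Prose-only mirror: 2 x (R1..R36), max 72 — numeracy omitted."""
    _require_bank_items(bank, MIRROR_S_READING, "prose mirror score")
    return _fixed_weight_score(responses, MIRROR_S_READING, ())


def classify_level(score: float, scale: LevelScale | None = None) -> Level:
    """Map a 0-100 score to its level: <=59 inadequate, 60-74 marginal, else adequate."""
    scale = scale or LevelScale()
    if not (0 <= score <= scale.score_max):
        raise ScoringError(f"score {score} outside [0, {scale.score_max}]")
    if score <= scale.inadequate_max:
        return Level.INADEQUATE
    if score <= scale.marginal_max:
        return Level.MARGINAL
    return Level.ADEQUATE


def classify_levels(scores: ScoreVector, scale: LevelScale | None = None) -> list[Level]:
    return [classify_level(s, scale) for s in scores.scores]


def admin_time(
    n_reading: int, n_numeracy: int, model: AdminTimeModel | None = None
) -> int:
    """Maximum administration time in whole minutes for a reduced instrument.

    Each part's full-length time is prorated by the fraction of its items
    retained and rounded up to a whole minute per part (a part with no items
    costs nothing).
    """
    model = model or AdminTimeModel()
    if n_reading < 0 or n_numeracy < 0:
        raise ScoringError("item counts must be non-negative")
    if n_reading > model.n_reading_full or n_numeracy > model.n_numeracy_full:
        raise ScoringError("item counts exceed the full-length instrument")
    minutes = 0
    if n_reading:
        minutes += math.ceil(model.reading_minutes_full * n_reading / model.n_reading_full)
    if n_numeracy:
        minutes += math.ceil(model.numeracy_minutes_full * n_numeracy / model.n_numeracy_full)
    return minutes
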