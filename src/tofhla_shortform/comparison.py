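"""Side-by-side comparison of instrument versions on one cohort.

Scores the full-length instrument, the two fixed-weight mirrors of the
American short form, and an integer-weighted short form on the same response
matrix, correlates each reduced version against the full-length score, and
tabulates item counts and administration times — one row per version.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .items import ItemBank, Part, ResponseMatrix, ShortFormModel
from .psychometrics import PsychometricsError, pearson_with_ci
from .scoring import (
    MIRROR_S_NUMERACY,
    MIRROR_S_READING,
    admin_time,
    score_full,
    score_mirror_prose,
    score_mirror_s,
    score_shortform,
)

__all__ = ["ModelOverviewRow", "compare_models", "overview_frame"]


@dataclass(frozen=True)
class ModelOverviewRow:
    """One instrument version: size, administration time, correlation with full length."""

    model_name: str
    n_reading: int
    n_numeracy: int
    admin_minutes: int
    r_vs_full: float | None = None
    ci95: tuple[float, float] | None = None
    note: str = ""


def _counts(model: ShortFormModel, bank: ItemBank) -> tuple[int, int]:
    parts = [bank[i].part for i in model.item_ids]
    return parts.count(Part.READING), parts.count(Part.NUMERACY)


def compare_models(
    responses: ResponseMatrix, bank: ItemBank, shortform: ShortFormModel
) -> list[ModelOverviewRow]:
    """Overview rows for full-length, both mirrors, and the given short form.

    The full-length row is the reference (its correlation column is empty).
    A version whose scores are constant on this cohort gets a flagged row
    instead of an undefined correlation.
    """
    full = score_full(responses, bank)
    rows = [
        ModelOverviewRow(
            "full-length",
            n_reading=len(bank.reading_items),
            n_numeracy=len(bank.numeracy_items),
            admin_minutes=admin_time(len(bank.reading_items), len(bank.numeracy_items)),
        )
    ]
    n_r_sf, n_n_sf = _counts(shortform, bank)
    candidates = [
        ("mirror-S (36+4)", len(MIRROR_S_READING), len(MIRROR_S_NUMERACY),
         score_mirror_s(responses, bank)),
        ("mirror-prose (36+0)", len(MIRROR_S_READING), 0,
         score_mirror_prose(responses, bank)),
        ("short form", n_r_sf, n_n_sf, score_shortform(responses, shortform)),
    ]
    for name, n_r, n_n, scores in candidates:
        minutes = admin_time(n_r, n_n)
        try:
            r, ci, _ = pearson_with_ci(scores, full)
        except PsychometricsError as exc:
            rows.append(ModelOverviewRow(name, n_r, n_n, minutes, note=str(exc)))
            continue
        rows.append(ModelOverviewRow(name, n_r, n_n, minutes, r_vs_full=r, ci95=ci))
    return rows


def overview_frame(rows: list[ModelOverviewRow]) -> pd.DataFrame:
    """The overview as a DataFrame ready for CSV export."""
    return pd.DataFrame(
        {
            "model_name": [r.model_name for r in rows],
            "n_reading": [r.n_reading for r in rows],
            "n_numeracy": [r.n_numeracy for r in rows],
            "admin_minutes": [r.admin_minutes for r in rows],
            "r_vs_full": [r.r_vs_full for r in rows],
            "ci95_low": [r.ci95[0] if r.ci95 else None for r in rows],
            "ci95_high": [r.ci95[1] if r.ci95 else None for r in rows],
            "note": [r.note for r in rows],
        }
    )
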