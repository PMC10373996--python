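"""Item banks, response matrices, score vectors and short-form model files.

The full-length TOFHLA instrument has two parts: numeracy (interviewer
administered) and reading comprehension (cloze items). This module holds the
in-memory data model for the instrument and the participants' binary item
responses, plus the JSON/CSV readers and writers for them. Everything
downstream (scoring, the exhaustive short-form search, validation statistics)
consumes these types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Part",
    "Item",
    "ItemBank",
    "ResponseMatrix",
    "ScoreVector",
    "LevelScale",
    "ShortFormModel",
    "SchemaError",
    "load_item_bank",
    "load_response_matrix",
    "load_model",
    "save_model",
    "packaged_bank",
    "packaged_short_form",
]

_DATA_DIR = Path(__file__).parent / "data"


class SchemaError(ValueError):
    """A file or in-memory object violates the documented schema."""


class Part(str, Enum):
    READING = "reading"
    NUMERACY = "numeracy"


@dataclass(frozen=True)
class Item:
    """One instrument item.

    ``position`` is the administration order within the item's part (1-based).
    Reading items must carry a ``set_id`` (the sentence-set they belong to);
    numeracy items may leave it ``None``.
    """

    item_id: str
    part: Part
    position: int
    set_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SchemaError(f"item {self.item_id!r}: position must be >= 1")
        if self.part is Part.READING and self.set_id is None:
            raise SchemaError(f"reading item {self.item_id!r} has no set_id")


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of items forming one instrument."""

    items: tuple[Item, ...]
    name: str = "bank"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        positions: dict[Part, set[int]] = {Part.READING: set(), Part.NUMERACY: set()}
        for it in self.items:
            if it.item_id in seen:
                raise SchemaError(f"duplicate item_id {it.item_id!r}")
            seen.add(it.item_id)
            if it.position in positions[it.part]:
                raise SchemaError(
                    f"duplicate position {it.position} within part {it.part.value!r}"
                    f" (item {it.item_id!r})"
                )
            positions[it.part].add(it.position)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def part_items(self, part: Part) -> list[Item]:
        return sorted((it for it in self.items if it.part is part), key=lambda i: i.position)

    @property
    def reading_items(self) -> list[Item]:
        return self.part_items(Part.READING)

    @property
    def numeracy_items(self) -> list[Item]:
        return self.part_items(Part.NUMERACY)


@dataclass(frozen=True)
class ResponseMatrix:
    """Participants x items binary (0/1) response matrix."""

    participant_ids: tuple[str, ...]
    item_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (len(self.participant_ids), len(self.item_ids)):
            raise SchemaError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.participant_ids)} participants x {len(self.item_ids)} items"
            )
        if vals.size and not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise SchemaError(
                f"non-binary response at participant "
                f"{self.participant_ids[bad[0]]!r}, item {self.item_ids[bad[1]]!r}"
            )
        if len(set(self.participant_ids)) != len(self.participant_ids):
            raise SchemaError("duplicate participant_ids")
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def column(self, item_id: str) -> np.ndarray:
        try:
            j = self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"item {item_id!r} not in response matrix") from None
        return self.values[:, j]

    def submatrix(self, item_ids: Sequence[str]) -> np.ndarray:
        """Column-select as a dense float array in the given item order."""
        return np.column_stack([self.column(i) for i in item_ids]).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.participant_ids), columns=list(self.item_ids)
        )


@dataclass(frozen=True)
class ScoreVector:
    """Per-participant scores on the 0-100 instrument scale."""

    participant_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.participant_ids),):
            raise SchemaError("scores length does not match participant_ids")
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return len(self.participant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"participant_id": list(self.participant_ids), "score": self.scores}
        )


@dataclass(frozen=True)
class LevelScale:
    """Cut-offs dividing the 0-100 score into the three health-literacy levels.

    Defaults are the standard instrument convention: inadequate 0-59,
    marginal 60-74, adequate 75-100.
    """

    inadequate_max: int = 59
    marginal_max: int = 74
    score_max: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.inadequate_max < self.marginal_max < self.score_max):
            raise SchemaError(
                "level scale requires 0 < inadequate_max < marginal_max < score_max"
            )


@dataclass(frozen=True)
class ShortFormModel:
    """An integer-weighted linear scoring rule: Y = intercept + sum(w_j * C_j).

    Weights are stored sparsely; an item absent from ``weights`` is not part
    of the short form. An explicit weight of 0 means the item is administered
    (it completes a sentence-set) but does not contribute points.
    """

    intercept: int
    weights: Mapping[str, int]
    scale: LevelScale = field(default_factory=LevelScale)
    provenance: str = ""

    def __post_init__(self) -> None:
        _require_int(self.intercept, "intercept")
        for item_id, w in self.weights.items():
            _require_int(w, f"weight of {item_id!r}")
        object.__setattr__(self, "weights", dict(self.weights))

    @property
    def item_ids(self) -> list[str]:
        return list(self.weights)

    @property
    def n_items(self) -> int:
        return len(self.weights)

    @property
    def max_score(self) -> int:
        return self.intercept + sum(w for w in self.weights.values() if w > 0)

    @property
    def min_score(self) -> int:
        return self.intercept + sum(w for w in self.weights.values() if w < 0)


def _require_int(value: object, what: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        if isinstance(value, float) and float(value).is_integer():
            raise SchemaError(f"{what} must be an integer, got float {value!r}")
        raise SchemaError(f"{what} must be an integer, got {value!r}")
    return int(value)


# ---------------------------------------------------------------------------
# file I/O


def load_item_bank(path: str | Path) -> ItemBank:
    """Read a bank JSON file: {"name", "items": [{item_id, part, position, set_id}]}."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict) or "items" not in raw:
        raise SchemaError(f"{path}: bank file must be an object with an 'items' array")
    items = []
    for rec in raw["items"]:
        try:
            part = Part(rec["part"])
        except ValueError:
            raise SchemaError(
                f"{path}: unknown part {rec.get('part')!r} for item {rec.get('item_id')!r}"
            ) from None
        items.append(
            Item(
                item_id=str(rec["item_id"]),
                part=part,
                position=int(rec["position"]),
                set_id=rec.get("set_id"),
            )
        )
    return ItemBank(items=tuple(items), name=str(raw.get("name", "bank")))


def save_item_bank(bank: ItemBank, path: str | Path) -> None:
    recs = [
        {"item_id": it.item_id, "part": it.part.value, "position": it.position, "set_id": it.set_id}
        for it in bank.items
    ]
    Path(path).write_text(json.dumps({"name": bank.name, "items": recs}, indent=1))


def load_response_matrix(path: str | Path, bank: ItemBank | None = None) -> ResponseMatrix:
    """Read a response CSV (header ``participant_id,<item ids...>``; body 0/1).

    Missing values are rejected rather than imputed: the scoring and search
    machinery assumes complete cases.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.empty or df.shape[1] < 2:
        raise SchemaError(f"{path}: empty or column-less response file")
    first = df.columns[0]
    if first != "participant_id":
        raise SchemaError(f"{path}: first column must be 'participant_id', got {first!r}")
    item_ids = [str(c) for c in df.columns[1:]]
    if bank is not None:
        known = set(bank.item_ids)
        unknown = [c for c in item_ids if c not in known]
        if unknown:
            raise SchemaError(f"{path}: columns not in bank: {unknown}")
    body = df[df.columns[1:]]
    if body.isna().any().any():
        row, col = next(zip(*np.where(body.isna().to_numpy())))
        raise SchemaError(f"{path}: missing response at row {row + 2}, column {item_ids[col]!r}")
    vals = body.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        row, col = np.argwhere(~np.isin(vals, (0, 1)))[0]
        raise SchemaError(
            f"{path}: non-binary value {vals[row, col]!r} at row {row + 2}, "
            f"column {item_ids[col]!r}"
        )
    return ResponseMatrix(
        participant_ids=tuple(df[first].astype(str)),
        item_ids=tuple(item_ids),
        values=vals,
    )


def save_response_matrix(matrix: ResponseMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.insert(0, "participant_id", list(matrix.participant_ids))
    df.to_csv(path, index=False)


def load_model(path: str | Path) -> ShortFormModel:
    """Read a short-form model JSON file."""
    raw = json.loads(Path(path).read_text())
    scale_raw = raw.get("scale", {})
    scale = LevelScale(
        inadequate_max=_require_int(scale_raw.get("inadequate_max", 59), "inadequate_max"),
        marginal_max=_require_int(scale_raw.get("marginal_max", 74), "marginal_max"),
        score_max=_require_int(scale_raw.get("score_max", 100), "score_max"),
    )
    weights = {
        str(k): _require_int(v, f"weight of {k!r}") for k, v in raw.get("weights", {}).items()
    }
    return ShortFormModel(
        intercept=_require_int(raw.get("intercept", 0), "intercept"),
        weights=weights,
        scale=scale,
        provenance=str(raw.get("provenance", "")),
    )


def save_model(model: ShortFormModel, path: str | Path) -> None:
    payload = {
        "intercept": model.intercept,
        "weights": dict(model.weights),
        "scale": {
            "inadequate_max": model.scale.inadequate_max,
            "marginal_max": model.scale.marginal_max,
            "score_max": model.scale.score_max,
        },
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def packaged_bank() -> ItemBank:
    """The packaged 67-item bank (50 reading, 17 numeracy, 19 sentence-sets)."""
    return load_item_bank(_DATA_DIR / "ds_tofhla_bank.json")


def packaged_short_form() -> ShortFormModel:
    """The packaged 20-item published short-form scoring rule."""
    return load_model(_DATA_DIR / "ds_tofhla_short.json")


def packaged_level_pairs() -> pd.DataFrame:
    """The packaged true/predicted level pairs realizing the published confusion matrix."""
    return pd.read_csv(_DATA_DIR / "level_pairs.csv", dtype=str)
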