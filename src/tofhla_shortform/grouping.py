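"""Sentence-sets of reading items: the atomic units of the short-form search.

Reading-comprehension items are cloze blanks inside sentences, so removing a
single item in the middle of a sentence would destroy its meaning. Items are
therefore grouped into *sets* — maximal runs of consecutive items that form
one sentence — and the exhaustive search selects whole sets, never single
items. Set membership is data (carried on each item in the bank file), not
inferred from the questionnaire text.
"""

from __future__ import annotations

from dataclasses import dataclass

from .items import ItemBank

__all__ = ["ItemSet", "GroupingError", "group_items", "set_size_distribution"]


class GroupingError(ValueError):
    """The bank's set assignment is not a contiguous partition."""


@dataclass(frozen=True)
class ItemSet:
    """One sentence-set: an ordered run of consecutive reading items."""

    set_id: str
    item_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.item_ids)


def group_items(bank: ItemBank) -> list[ItemSet]:
    """Partition the bank's reading items into their sentence-sets.

    Validates that the assignment is a true partition (every reading item in
    exactly one set) and that each set is contiguous in administration order.
    Returns the sets ordered by the position of their first item.

    Raises
    ------
    GroupingError
        If a reading item lacks a set, a set's items are not consecutive, or
        a set's positions interleave with another set's.
    """
    reading = bank.reading_items
    by_set: dict[str, list] = {}
    for it in reading:
        if it.set_id is None:
            raise GroupingError(f"reading item {it.item_id!r} is not assigned to a set")
        by_set.setdefault(it.set_id, []).append(it)

    sets: list[ItemSet] = []
    for set_id, members in by_set.items():
        members.sort(key=lambda i: i.position)
        positions = [m.position for m in members]
        if positions != list(range(positions[0], positions[0] + len(positions))):
            raise GroupingError(
                f"set {set_id!r} is not contiguous in administration order: "
                f"positions {positions}"
            )
        sets.append(ItemSet(set_id=set_id, item_ids=tuple(m.item_id for m in members)))

    sets.sort(key=lambda s: bank[s.item_ids[0]].position)
    # contiguous sets partition the reading items iff their position ranges tile
    expected_next = None
    for s in sets:
        first = bank[s.item_ids[0]].position
        if expected_next is not None and first != expected_next:
            raise GroupingError(
                f"set {s.set_id!r} overlaps or leaves a gap before position {first}"
            )
        expected_next = first + s.size
    return sets


def set_size_distribution(sets: list[ItemSet]) -> dict[int, int]:
    """Histogram of set sizes. Sum of size x count equals the reading item count."""
    hist: dict[int, int] = {}
    for s in sets:
        hist[s.size] = hist.get(s.size, 0) + 1
    return dict(sorted(hist.items()))
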