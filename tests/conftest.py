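import numpy as np
import pytest

from tofhla_shortform import (
    Item,
    ItemBank,
    Part,
    ResponseMatrix,
    packaged_bank,
    packaged_short_form,
)


@pytest.fixture(scope="session")
def bank():
    return packaged_bank()


@pytest.fixture(scope="session")
def short_form():
    return packaged_short_form()


def make_bank(set_sizes, n_numeracy=0, name="mini"):
    """A reading bank with consecutive sentence-sets of the given sizes."""
    items = []
    pos = 0
    for k, size in enumerate(set_sizes, start=1):
        for _ in range(size):
            pos += 1
            items.append(Item(f"R{pos}", Part.READING, pos, f"S{k}"))
    for j in range(1, n_numeracy + 1):
        items.append(Item(f"N{j}", Part.NUMERACY, j, None))
    return ItemBank(tuple(items), name=name)


def random_responses(bank, n, seed, p=0.6):
    rng = np.random.default_rng(seed)
    values = (rng.random((n, len(bank.item_ids))) < p).astype(int)
    pids = tuple(f"p{i}" for i in range(n))
    return ResponseMatrix(pids, tuple(bank.item_ids), values)


@pytest.fixture
def mini_bank():
    return make_bank([1, 1, 2, 2, 2, 3, 3, 2])  # 8 sets, 16 items


@pytest.fixture(scope="session")
def all_correct(bank):
    values = np.ones((1, len(bank.item_ids)), dtype=int)
    return ResponseMatrix(("p1",), tuple(bank.item_ids), values)


@pytest.fixture(scope="session")
def all_wrong(bank):
    values = np.zeros((1, len(bank.item_ids)), dtype=int)
    return ResponseMatrix(("p1",), tuple(bank.item_ids), values)
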