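import numpy as np
import pytest

from dtpd.concept_mapping import SortingDataset


def make_sorts(partitions: dict[str, list[list[str]]]) -> SortingDataset:
    """Build a SortingDataset from explicit piles per sorter."""
    assignment = {}
    items: dict[str, None] = {}
    for sorter, piles in partitions.items():
        for idx, pile in enumerate(piles):
            for item in pile:
                assignment[(sorter, item)] = f"p{idx}"
                items.setdefault(item)
    return SortingDataset(
        items=tuple(items), sorters=tuple(partitions), assignment=assignment
    )


def random_sorts(rng: np.random.Generator, n_items: int, n_sorters: int,
                 n_piles: int) -> SortingDataset:
    """Sorters assigning each item independently to a uniform random pile."""
    items = tuple(f"i{j}" for j in range(n_items))
    sorters = tuple(f"s{j}" for j in range(n_sorters))
    assignment = {}
    for s in sorters:
        codes = rng.integers(0, n_piles, n_items)
        for item, c in zip(items, codes):
            assignment[(s, item)] = f"p{c}"
    return SortingDataset(items=items, sorters=sorters, assignment=assignment)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
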