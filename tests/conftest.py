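import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stcooccur as st

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_pa():
    """10 sites x 3 entities: a and b identical, c disjoint from both."""
    a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
    return st.PresenceAbsenceMatrix(
        site_ids=[f"s{i}" for i in range(10)],
        entity_ids=["a", "b", "c"],
        values=np.column_stack([a, a, ~a]),
    )


@pytest.fixture
def toy_counts():
    """5 spots x 4 genes with simple hand-set counts."""
    counts = np.array(
        [
            [3, 2, 0, 1],
            [0, 0, 5, 0],
            [1, 1, 0, 2],
            [0, 4, 1, 0],
            [2, 0, 0, 3],
        ]
    )
    return st.SpotCountMatrix(
        spot_ids=[f"s{i}" for i in range(5)],
        gene_ids=["LIG", "REC", "GX", "GY"],
        counts=counts,
    )


def enumeration_cooccurrence_distribution(n_sites: int, n1: int, n2: int):
    """Independent oracle: exhaustively place entity 1 on every n1-subset and
    entity 2 on every n2-subset of the sites (as bitmasks) and tabulate the
    overlap; returns {j: probability}."""
    from itertools import combinations

    sites = range(n_sites)
    counts = {}
    total = 0
    for mask_a in combinations(sites, n1):
        set_a = set(mask_a)
        for mask_b in combinations(sites, n2):
            j = len(set_a.intersection(mask_b))
            counts[j] = counts.get(j, 0) + 1
            total += 1
    return {j: c / total for j, c in counts.items()}
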