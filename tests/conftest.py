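"""Shared fixtures: the three-gene worked example and brute-force oracles."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from bicrules.datatypes import BooleanMatrix, ItemMatrix
from bicrules.discretize import post_discretize


@pytest.fixture
def toy_item_matrix() -> ItemMatrix:
    """Three genes, six samples: reconstruction of the worked example.

    The boolean gene matrix is chosen so that the three canonical maximal
    biclusters appear after sign-doubling:
      {g1+, g2-, g3+} x {s_tr1, s_tr3}  (both treated; homogeneous)
      {g1+, g2+, g3-} x {s_nr1, s_nr3}  (both normal; homogeneous)
      {g1-, g2+, g3+} x {s_tr2, s_nr2}  (mixed classes; heterogeneous)
    """
    bits = pd.DataFrame(
        [
            [1, 0, 1],  # s_tr1
            [0, 1, 1],  # s_tr2
            [1, 0, 1],  # s_tr3
            [1, 1, 0],  # s_nr1
            [0, 1, 1],  # s_nr2
            [1, 1, 0],  # s_nr3
        ],
        index=["s_tr1", "s_tr2", "s_tr3", "s_nr1", "s_nr2", "s_nr3"],
        columns=["g1", "g2", "g3"],
    )
    labels = pd.Series(
        ["disease", "disease", "disease", "normal", "normal", "normal"],
        index=bits.index,
    )
    return post_discretize(BooleanMatrix(bits, labels, ("disease", "normal")))


def brute_force_maximal(bits: pd.DataFrame, min_items: int, min_support: int):
    """Oracle: inclusion-maximal all-1 biclusters by exhaustive enumeration.

    Every closed pair (G, S) arises as (items all-1 on S', samples all-1 on
    those items) for some sample subset S'; closed pairs are exactly the
    inclusion-maximal biclusters.
    """
    arr = bits.to_numpy()
    n_samples, n_items = arr.shape
    pairs = set()
    for r in range(1, n_samples + 1):
        for subset in itertools.combinations(range(n_samples), r):
            sub = arr[list(subset)]
            g = np.flatnonzero(sub.all(axis=0))
            if len(g) == 0:
                continue
            s = np.flatnonzero(arr[:, g].all(axis=1))
            pairs.add((frozenset(g), frozenset(s)))
    out = set()
    for g, s in pairs:
        if len(g) >= min_items and len(s) >= min_support:
            out.add(
                (
                    frozenset(bits.columns[j] for j in g),
                    frozenset(bits.index[i] for i in s),
                )
            )
    return out


def brute_force_frequent_closed(bits: pd.DataFrame, min_support: int):
    """Oracle: all frequent closed itemsets, Apriori-style over all itemsets."""
    arr = bits.to_numpy()
    n_items = arr.shape[1]
    support: dict[frozenset, int] = {}
    for r in range(1, n_items + 1):
        for combo in itertools.combinations(range(n_items), r):
            s = int(arr[:, list(combo)].all(axis=1).sum())
            if s >= min_support:
                support[frozenset(combo)] = s
    closed = set()
    for itemset, s in support.items():
        if not any(
            itemset < other and support[other] == s for other in support
        ):
            closed.add(frozenset(bits.columns[j] for j in itemset))
    return closed
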