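"""Enumeration of inclusion-maximal all-1 biclusters of a boolean item matrix.

An inclusion-maximal bicluster (G, S) -- no strict superset pair is also
all-1 -- corresponds one-to-one to a closed itemset G together with its full
support set S.  The enumerator therefore walks the closed-itemset lattice
with prefix-preserving closure extensions (each closed set is visited
exactly once), pruning on the support threshold, and reports every closed
set meeting both the item and support minima.  The output set is anchored
by a brute-force oracle in the test-suite; any enumeration strategy with
the same output set is conformant.
"""
from __future__ import annotations

import pandas as pd

from .datatypes import Bicluster, ItemMatrix, MFCHOI

__all__ = ["bimax_enumerate", "filter_homogeneous", "ResultCapExceeded"]


class ResultCapExceeded(RuntimeError):
    pass


def bimax_enumerate(
    im: ItemMatrix | pd.DataFrame,
    min_items: int = 1,
    min_support: int = 1,
    max_results: int = 10**6,
) -> list[Bicluster]:
    """All inclusion-maximal all-1 biclusters with |G| >= min_items and
    |S| >= min_support, in a deterministic order (support desc, item count
    desc, lexicographic item names).

    Accepts either an ItemMatrix or any plain sample x item 0/1 DataFrame.
    """
    if min_items < 1 or min_support < 1:
        raise ValueError("min_items and min_support must be >= 1")
    frame = im.bits if isinstance(im, ItemMatrix) else im
    bits = frame.to_numpy()
    n_samples, n_items = bits.shape
    item_names = list(frame.columns)
    sample_ids = list(frame.index)

    # per-item support as a bitmask over samples
    supp = []
    for j in range(n_items):
        mask = 0
        col = bits[:, j]
        for i in range(n_samples):
            if col[i]:
                mask |= 1 << i
        supp.append(mask)

    full = (1 << n_samples) - 1
    found: list[tuple[tuple[int, ...], int]] = []

    def closure_of(mask: int) -> list[int]:
        return [k for k in range(n_items) if supp[k] & mask == mask]

    def emit(items: list[int], mask: int) -> None:
        if len(items) >= min_items and mask.bit_count() >= min_support:
            found.append((tuple(items), mask))
            if len(found) > max_results:
                raise ResultCapExceeded(
                    f"more than {max_results} biclusters; raise min_support"
                )

    def recurse(clo: list[int], mask: int, start: int) -> None:
        clo_set = set(clo)
        for j in range(start, n_items):
            if j in clo_set:
                continue
            new_mask = mask & supp[j]
            if new_mask.bit_count() < min_support:
                continue
            new_clo = closure_of(new_mask)
            # prefix-preserving check: the closure may not introduce an
            # item smaller than j that was absent from the parent closure
            if any(k < j and k not in clo_set for k in new_clo):
                continue
            emit(new_clo, new_mask)
            recurse(new_clo, new_mask, j + 1)

    root_clo = closure_of(full)
    if full.bit_count() >= 1:
        emit(root_clo, full)
        recurse(root_clo, full, 0)

    out = []
    for items, mask in found:
        G = frozenset(item_names[j] for j in items)
        S = frozenset(sample_ids[i] for i in range(n_samples) if mask >> i & 1)
        out.append(Bicluster(G=G, S=S))
    out.sort(key=lambda b: (-len(b.S), -len(b.G), tuple(sorted(b.G))))
    return out


def filter_homogeneous(bics: list[Bicluster], labels) -> list[MFCHOI]:
    """Keep biclusters whose samples all share one class; attach the class.

    Heterogeneous biclusters are discarded outright, never trimmed to a
    homogeneous subset.
    """
    out = []
    for b in bics:
        classes = {labels[s] for s in b.S}
        if len(classes) == 1:
            out.append(MFCHOI(bicluster=b, class_label=next(iter(classes))))
    return out
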