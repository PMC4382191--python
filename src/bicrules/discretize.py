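"""Boolean discretization of the selected-gene matrix.

The normalized gene x sample matrix is transposed and thresholded at zero
(sample above the gene's mean -> 1), then the gene columns are doubled into
signed items: the '+' column copies the boolean column ('1' = up-regulated /
hyper-methylated present) and the '-' column is its complement ('1' =
down-regulated / hypo-methylated present).  The doubling makes both
directions representable as 1s, which is what the all-1 bicluster miner
requires.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BooleanMatrix, ItemMatrix, LabeledMatrix

__all__ = ["binarize", "post_discretize"]


def binarize(m: LabeledMatrix) -> BooleanMatrix:
    """Threshold the (normalized) matrix at zero, transposed to samples x genes.

    Values > 0 map to 1 and values < 0 to 0.  Exact zeros map to 0, so '1'
    strictly means above the gene's mean; on continuous data an exact zero
    has measure zero.
    """
    if not isinstance(m, LabeledMatrix):
        raise TypeError("binarize expects a LabeledMatrix")
    bits = (m.values.T > 0).astype(int)
    return BooleanMatrix(bits, m.labels.copy(), m.classes)


def post_discretize(b: BooleanMatrix) -> ItemMatrix:
    """Double the gene columns into signed '+'/'-' item columns."""
    if not isinstance(b, BooleanMatrix):
        raise TypeError("post_discretize expects a BooleanMatrix (already signed?)")
    genes = b.gene_ids
    plus = b.bits.copy()
    plus.columns = [f"{g}+" for g in genes]
    minus = (1 - b.bits).copy()
    minus.columns = [f"{g}-" for g in genes]
    bits = pd.concat([plus, minus], axis=1)
    items = [(g, "+") for g in genes] + [(g, "-") for g in genes]
    return ItemMatrix(bits, items, b.labels.copy(), b.classes)
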