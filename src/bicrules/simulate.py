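"""Synthetic two-class fixtures with known ground truth.

Three generators make every pipeline stage testable without any download:
numeric matrices mixing normally and non-normally distributed genes with
planted up/down effects, boolean item matrices with planted homogeneous
all-1 blocks, and paired expression/methylation matrices with planted
inverse-regulation genes.  All generators are pure functions of their
parameters and seed, and every fixture records the truth that determines
the expected output of the stage under test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BooleanMatrix, ItemMatrix, LabeledMatrix
from .discretize import post_discretize

__all__ = [
    "SyntheticTruth",
    "simulate_two_class",
    "simulate_item_matrix",
    "simulate_paired",
]


@dataclass
class SyntheticTruth:
    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> up/down/null
    nonnormal_genes: set[str] = field(default_factory=set)
    planted_biclusters: list[tuple[frozenset, frozenset, str]] = field(default_factory=list)
    inverse_genes: dict[str, str] = field(default_factory=dict)  # gene -> up_hypo/down_hyper
    params: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "nonnormal_genes": sorted(self.nonnormal_genes),
            "planted_biclusters": [
                {"items": sorted(g), "samples": sorted(s), "class": c}
                for g, s, c in self.planted_biclusters
            ],
            "inverse_genes": self.inverse_genes,
            "params": self.params,
        }


_LOGNORM_MEAN = float(np.exp(0.5))            # E[lognormal(0,1)]
_LOGNORM_SD = float(np.sqrt((np.e - 1) * np.e))  # SD[lognormal(0,1)]


def _base_draw(rng: np.random.Generator, nonnormal: bool, size: int) -> np.ndarray:
    """Unit-variance, zero-mean base noise: Gaussian or shifted lognormal.

    The lognormal(0,1) family has skewness ~6.2, strong enough for the
    Jarque-Bera partition to separate it from the Gaussian genes at a few
    dozen samples.
    """
    if nonnormal:
        return (rng.lognormal(0.0, 1.0, size) - _LOGNORM_MEAN) / _LOGNORM_SD
    return rng.normal(0.0, 1.0, size)


def simulate_two_class(
    n_genes: int = 1000,
    n1: int = 20,
    n2: int = 20,
    frac_de: float = 0.1,
    delta: float = 2.0,
    frac_nonnormal: float = 0.3,
    seed: int = 0,
    classes: tuple[str, str] = ("disease", "normal"),
) -> tuple[LabeledMatrix, SyntheticTruth]:
    """Two-class matrix with planted differential expression.

    DE genes receive a +/- ``delta`` (in within-group sd units) mean shift
    in the experimental class, the sign split evenly between up and down;
    ``frac_nonnormal`` of genes draw their noise from the shifted-lognormal
    family instead of the Gaussian.
    """
    if min(n_genes, n1, n2) <= 0 or not (0 <= frac_de <= 1) or not (0 <= frac_nonnormal <= 1):
        raise ValueError("invalid generator parameters")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"E{j:03d}" for j in range(n1)] + [f"C{j:03d}" for j in range(n2)]
    labels = pd.Series(
        [classes[0]] * n1 + [classes[1]] * n2, index=samples, name="class"
    )
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    up_set = set(de_idx[: n_de // 2])
    down_set = set(de_idx[n_de // 2:])
    nn_idx = set(rng.choice(n_genes, size=int(round(frac_nonnormal * n_genes)), replace=False))

    values = np.empty((n_genes, n1 + n2))
    truth = SyntheticTruth(params={
        "n_genes": n_genes, "n1": n1, "n2": n2, "frac_de": frac_de,
        "delta": delta, "frac_nonnormal": frac_nonnormal, "seed": seed,
    })
    for i, gene in enumerate(genes):
        nonnormal = i in nn_idx
        row = _base_draw(rng, nonnormal, n1 + n2)
        if i in up_set:
            row[:n1] += delta
            truth.de_genes[gene] = "up"
        elif i in down_set:
            row[:n1] -= delta
            truth.de_genes[gene] = "down"
        else:
            truth.de_genes[gene] = "null"
        if nonnormal:
            truth.nonnormal_genes.add(gene)
        values[i] = row
    matrix = LabeledMatrix(
        pd.DataFrame(values, index=genes, columns=samples), labels, classes
    )
    return matrix, truth


def simulate_item_matrix(
    n_genes: int = 40,
    n1: int = 20,
    n2: int = 20,
    k_rules: int = 2,
    items_per_rule: int = 3,
    samples_per_rule: int = 20,
    noise: float = 0.02,
    seed: int = 0,
    classes: tuple[str, str] = ("disease", "normal"),
) -> tuple[ItemMatrix, SyntheticTruth]:
    """Signed item matrix with planted homogeneous all-1 blocks.

    The underlying boolean gene matrix starts from i.i.d. fair random bits;
    each planted block fixes ``items_per_rule`` signed gene-items to their
    '1' state on ``samples_per_rule`` samples of a single class.  A class's
    blocks tile it in a circulant design (consecutive blocks start at evenly
    spaced offsets of a random class ordering), so with the defaults every
    sample lies in at least two of its class's blocks while consecutive
    blocks still differ on about a third of the class -- enough overlap for
    full coverage, enough separation that each block stays its own closed
    itemset instead of merging with its neighbours.  Blocks are confined to
    their class constructively: an other-class sample that satisfies a
    block's full item set by background chance has one of the block's items
    flipped, so at zero noise every planted block closes to a homogeneous
    maximal bicluster.  Symmetric bit-flip noise is then applied on the '+'
    domain and the '-' columns recomputed as complements, which preserves
    the item-matrix invariant.
    """
    if items_per_rule < 2 or samples_per_rule < 1:
        raise ValueError("items_per_rule >= 2 and samples_per_rule >= 1 required")
    if not (0 <= noise < 0.5):
        raise ValueError("noise must lie in [0, 0.5)")
    class_sizes = {classes[0]: n1, classes[1]: n2}
    if samples_per_rule > min(n1, n2):
        raise ValueError("planted blocks exceed class size")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"E{j:03d}" for j in range(n1)] + [f"C{j:03d}" for j in range(n2)]
    labels = pd.Series([classes[0]] * n1 + [classes[1]] * n2, index=samples, name="class")
    bits = rng.integers(0, 2, size=(n1 + n2, n_genes))

    truth = SyntheticTruth(params={
        "n_genes": n_genes, "n1": n1, "n2": n2, "k_rules": k_rules,
        "items_per_rule": items_per_rule, "samples_per_rule": samples_per_rule,
        "noise": noise, "seed": seed,
    })
    class_rows = {
        classes[0]: np.arange(n1),
        classes[1]: np.arange(n1, n1 + n2),
    }
    # non-overlapping gene assignment when possible keeps planted blocks
    # independent of one another
    if k_rules * items_per_rule <= n_genes:
        gene_pool = rng.permutation(n_genes)
        gene_choices = [
            gene_pool[r * items_per_rule:(r + 1) * items_per_rule]
            for r in range(k_rules)
        ]
    else:
        gene_choices = [
            rng.choice(n_genes, size=items_per_rule, replace=False)
            for _ in range(k_rules)
        ]
    # circulant sample cover per class
    class_order = {c: rng.permutation(class_rows[c]) for c in classes}
    rules_in_class = {c: sum(1 for r in range(k_rules) if classes[r % 2] == c) for c in classes}
    seen_in_class = {c: 0 for c in classes}
    planted = []
    for r in range(k_rules):
        cls = classes[r % 2]
        gsel = gene_choices[r]
        signs = rng.integers(0, 2, size=items_per_rule)  # 1 -> '+', 0 -> '-'
        order = class_order[cls]
        m_cls = rules_in_class[cls]
        start = int(round(seen_in_class[cls] * len(order) / m_cls))
        seen_in_class[cls] += 1
        rows = np.array([order[(start + j) % len(order)] for j in range(samples_per_rule)])
        for g, sgn in zip(gsel, signs):
            bits[rows, g] = sgn
        planted.append((gsel, signs, rows, cls))
    # confinement: every other-class sample must mismatch each block's
    # signature in at least `margin` items, so neither the block nor its
    # long sub-itemsets reach across the class boundary
    margin = min(2, items_per_rule - 1)
    for gsel, signs, rows, cls in planted:
        other = class_rows[classes[1] if cls == classes[0] else classes[0]]
        for row in other:
            matching = np.flatnonzero(bits[row, gsel] == signs)
            need = margin - (len(gsel) - len(matching))
            if need > 0:
                flip = rng.choice(matching, size=need, replace=False)
                for j in flip:
                    bits[row, gsel[j]] = 1 - signs[j]
    # record truth after confinement, before noise
    for gsel, signs, rows, cls in planted:
        items = frozenset(
            f"{genes[g]}{'+' if sgn else '-'}" for g, sgn in zip(gsel, signs)
        )
        truth.planted_biclusters.append(
            (items, frozenset(samples[i] for i in rows), cls)
        )
    if noise > 0:
        flips = rng.random(bits.shape) < noise
        bits = np.where(flips, 1 - bits, bits)

    boolean = BooleanMatrix(
        pd.DataFrame(bits, index=samples, columns=genes), labels, classes
    )
    return post_discretize(boolean), truth


def simulate_paired(
    n_genes: int = 300,
    n1: int = 20,
    n2: int = 20,
    k_inverse: int = 10,
    delta: float = 3.0,
    seed: int = 0,
    classes: tuple[str, str] = ("disease", "normal"),
) -> tuple[LabeledMatrix, LabeledMatrix, SyntheticTruth]:
    """Paired expression/methylation matrices with planted inverse regulation.

    Half of the ``k_inverse`` genes are up-regulated in expression and
    hypo-methylated in the experimental class; the other half mirrored.
    All remaining genes are null in both matrices.  Gene and sample ids are
    shared across the pair.
    """
    if k_inverse > n_genes:
        raise ValueError("k_inverse cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"E{j:03d}" for j in range(n1)] + [f"C{j:03d}" for j in range(n2)]
    labels = pd.Series([classes[0]] * n1 + [classes[1]] * n2, index=samples, name="class")
    expr = rng.normal(0.0, 1.0, size=(n_genes, n1 + n2))
    meth = rng.normal(0.0, 1.0, size=(n_genes, n1 + n2))
    chosen = rng.choice(n_genes, size=k_inverse, replace=False)
    truth = SyntheticTruth(params={
        "n_genes": n_genes, "n1": n1, "n2": n2, "k_inverse": k_inverse,
        "delta": delta, "seed": seed,
    })
    for rank, i in enumerate(chosen):
        if rank < k_inverse // 2 + k_inverse % 2:
            expr[i, :n1] += delta
            meth[i, :n1] -= delta
            truth.inverse_genes[genes[i]] = "up_hypo"
        else:
            expr[i, :n1] -= delta
            meth[i, :n1] += delta
            truth.inverse_genes[genes[i]] = "down_hyper"
    expr_m = LabeledMatrix(
        pd.DataFrame(expr, index=genes, columns=samples), labels.copy(), classes
    )
    meth_m = LabeledMatrix(
        pd.DataFrame(meth, index=genes, columns=samples), labels.copy(), classes
    )
    return expr_m, meth_m, truth
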