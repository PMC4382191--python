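"""Core containers shared across the pipeline.

The pipeline moves a two-class gene x sample matrix through selection,
discretization, mining, ranking and classification.  Each stage has its own
container; all of them keep explicit gene/sample/item identifiers so that
every downstream object can be traced back to the input matrix.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledMatrix",
    "PipelineConfig",
    "TestResult",
    "GroupSummary",
    "SelectionResult",
    "BooleanMatrix",
    "ItemMatrix",
    "Bicluster",
    "MFCHOI",
    "Rule",
    "ContingencyCounts",
]


class LoadError(ValueError):
    """Raised when an input file violates a matrix/label invariant."""


@dataclass
class LabeledMatrix:
    """A numeric gene x sample matrix with a two-class sample labelling.

    ``values`` is indexed by gene id (rows) and sample id (columns).
    ``classes`` orders the two class names as (experimental, control); the
    experimental class is the positive class everywhere downstream.
    """

    values: pd.DataFrame
    labels: pd.Series
    classes: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.labels = self.labels.reindex(self.values.columns)
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise LoadError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise LoadError(f"duplicate sample id: {dup!r}")
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()][0]
            raise LoadError(f"sample {missing!r} has no class label")
        if np.isnan(self.values.to_numpy()).any():
            gene = self.values.index[self.values.isna().any(axis=1)][0]
            raise LoadError(f"missing/non-numeric value in gene {gene!r}")
        present = set(self.labels.unique())
        if present != set(self.classes):
            raise LoadError(
                f"exactly two classes required; labels contain {sorted(present)}, "
                f"declared classes are {list(self.classes)}"
            )

    # ---- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def experimental(self) -> str:
        return self.classes[0]

    @property
    def control(self) -> str:
        return self.classes[1]

    def class_columns(self, cls: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == cls]

    def group_arrays(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (experimental, control) value vectors for one gene."""
        row = self.values.loc[gene]
        g1 = row[self.class_columns(self.experimental)].to_numpy(float)
        g2 = row[self.class_columns(self.control)].to_numpy(float)
        return g1, g2

    def subset_genes(self, genes: Sequence[str]) -> "LabeledMatrix":
        return LabeledMatrix(self.values.loc[list(genes)], self.labels.copy(), self.classes)

    def subset_samples(self, samples: Sequence[str]) -> "LabeledMatrix":
        return LabeledMatrix(
            self.values[list(samples)], self.labels[list(samples)], self.classes
        )


@dataclass
class PipelineConfig:
    """Tunable knobs of the whole pipeline; the seed is recorded in outputs."""

    p_cutoff: float = 0.05
    normality_alpha: float = 0.05
    variance_quantile: float = 0.1
    min_items: int = 2
    min_support: int = 8
    cv_folds: int = 4
    cv_repeats: int = 10
    permutations: int = 1000
    seed: int = 0
    weight_znorm: bool = False
    bayes_prior_df: int = 10
    bayes_neighborhood: int = 101

    def __post_init__(self) -> None:
        if not (0 < self.p_cutoff < 1):
            raise ValueError("p_cutoff must lie in (0, 1)")
        if not (0 < self.normality_alpha < 1):
            raise ValueError("normality_alpha must lie in (0, 1)")
        if self.min_items < 1 or self.min_support < 1:
            raise ValueError("min_items and min_support must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class GroupSummary:
    """Per-gene two-group summary behind the pooled t family."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float

    @classmethod
    def from_groups(cls, g1: np.ndarray, g2: np.ndarray) -> "GroupSummary":
        g1 = np.asarray(g1, float)
        g2 = np.asarray(g2, float)
        return cls(
            n1=len(g1),
            n2=len(g2),
            mean1=float(np.mean(g1)),
            mean2=float(np.mean(g2)),
            sd1=float(np.std(g1, ddof=1)) if len(g1) > 1 else 0.0,
            sd2=float(np.std(g2, ddof=1)) if len(g2) > 1 else 0.0,
        )

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2

    @property
    def pooled_sd(self) -> float:
        if self.df <= 0:
            return 0.0
        num = (self.n1 - 1) * self.sd1**2 + (self.n2 - 1) * self.sd2**2
        return math.sqrt(num / self.df)

    @property
    def se(self) -> float:
        return self.pooled_sd * math.sqrt(1.0 / self.n1 + 1.0 / self.n2)


@dataclass
class TestResult:
    """Outcome of one statistical test on one gene."""

    method: str
    statistic: float
    pvalue: float
    direction: str | None = None  # 'up' | 'down' | None
    applicable: bool = True

    def __post_init__(self) -> None:
        if self.applicable and not (math.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of range: {self.pvalue}")


@dataclass
class SelectionResult:
    """Intersected up/down gene sets plus the full per-test table.

    ``table`` has one row per surviving gene with columns partition,
    direction, per-test statistics/p-values and the seven membership flags.
    """

    normal_genes: set[str]
    nonnormal_genes: set[str]
    table: pd.DataFrame
    up_N: set[str]
    down_N: set[str]
    up_NN: set[str]
    down_NN: set[str]

    @property
    def total_N(self) -> set[str]:
        return self.up_N | self.down_N

    @property
    def total_NN(self) -> set[str]:
        return self.up_NN | self.down_NN

    @property
    def total(self) -> set[str]:
        return self.total_N | self.total_NN

    def validate(self) -> None:
        assert not (self.up_N & self.down_N)
        assert not (self.up_NN & self.down_NN)
        assert self.total_N <= self.normal_genes
        assert self.total_NN <= self.nonnormal_genes


@dataclass
class BooleanMatrix:
    """Sample x gene {0,1} matrix (the transposed, thresholded z-scores)."""

    bits: pd.DataFrame  # samples x genes
    labels: pd.Series
    classes: tuple[str, str]

    def __post_init__(self) -> None:
        vals = self.bits.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BooleanMatrix entries must be 0/1")
        self.bits = self.bits.astype(int)
        self.labels = self.labels.reindex(self.bits.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.bits.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.bits.columns)


@dataclass
class ItemMatrix:
    """Sample x signed-item boolean matrix (the post-discretized view).

    Columns come in two halves: first every gene's '+' item, then every
    gene's '-' item; for each sample and gene exactly one of the two is 1.
    """

    bits: pd.DataFrame  # samples x items, item columns named "GENE+"/"GENE-"
    items: list[tuple[str, str]]  # (gene_id, '+'|'-') in column order
    labels: pd.Series
    classes: tuple[str, str]

    def __post_init__(self) -> None:
        vals = self.bits.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("ItemMatrix entries must be 0/1")
        self.bits = self.bits.astype(int)
        self.labels = self.labels.reindex(self.bits.index)
        n_items = len(self.items)
        if n_items != self.bits.shape[1] or n_items % 2:
            raise ValueError("item list must match columns and have even length")
        half = n_items // 2
        genes_plus = [g for g, s in self.items[:half]]
        genes_minus = [g for g, s in self.items[half:]]
        if genes_plus != genes_minus or {s for _, s in self.items[:half]} - {"+"} or {
            s for _, s in self.items[half:]
        } - {"-"}:
            raise ValueError("first half of items must be '+', second half '-', same gene order")
        plus = self.bits.iloc[:, :half].to_numpy()
        minus = self.bits.iloc[:, half:].to_numpy()
        if not np.array_equal(plus + minus, np.ones_like(plus)):
            raise ValueError("for every sample/gene exactly one of (g,+),(g,-) must be 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.bits.index)

    @property
    def item_names(self) -> list[str]:
        return list(self.bits.columns)

    @property
    def n_genes(self) -> int:
        return len(self.items) // 2

    def subset_samples(self, samples: Sequence[str]) -> "ItemMatrix":
        return ItemMatrix(
            self.bits.loc[list(samples)], list(self.items), self.labels[list(samples)], self.classes
        )


@dataclass(frozen=True)
class Bicluster:
    """Inclusion-maximal all-1 submatrix: items G over samples S."""

    G: frozenset[str]
    S: frozenset[str]

    @property
    def support(self) -> int:
        return len(self.S)


@dataclass(frozen=True)
class MFCHOI:
    """A homogeneous maximal bicluster: all its samples share one class."""

    bicluster: Bicluster
    class_label: str


@dataclass
class ContingencyCounts:
    """2x2 counts of a rule against the full item matrix."""

    n: int
    n_A: int
    n_C: int
    n_AC: int

    def __post_init__(self) -> None:
        if min(self.n, self.n_A, self.n_C, self.n_AC) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_AC > min(self.n_A, self.n_C):
            raise ValueError("n_AC cannot exceed n_A or n_C")


@dataclass
class Rule:
    """A class-labelled special rule extracted from one MFCHOI."""

    id: int
    antecedent: frozenset[str]
    consequent: str
    source_samples: frozenset[str]
    measures: dict[str, float] = field(default_factory=dict)
    fractional_ranks: dict[str, float] = field(default_factory=dict)
    final_rank: float = math.nan
    position: int = 0
    weight: float = math.nan

    def copy(self) -> "Rule":
        return replace(
            self,
            measures=dict(self.measures),
            fractional_ranks=dict(self.fractional_ranks),
        )
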