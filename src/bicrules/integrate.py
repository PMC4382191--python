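"""Expression-methylation integration: inverse-regulation gene sets.

Methylation of a promoter generally suppresses transcription, so the
epigenetically controlled genes are those called up-regulated in expression
while hypo-methylated, or down-regulated while hyper-methylated.  The two
matrices are restricted to their shared genes and samples, each runs the
full selection stage independently, and the directional calls are
intersected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import LabeledMatrix, PipelineConfig, SelectionResult
from .stat_select import select_genes

__all__ = ["IntegrativeResult", "match_datasets", "inverse_regulation", "integrate"]


@dataclass
class IntegrativeResult:
    matched_genes: int
    matched_samples: int
    up_and_hypo: set[str] = field(default_factory=set)
    down_and_hyper: set[str] = field(default_factory=set)


def match_datasets(
    expr: LabeledMatrix, meth: LabeledMatrix
) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Restrict both matrices to shared gene ids and sample ids, same order.

    Matching is by exact identifier string.
    """
    genes = [g for g in expr.gene_ids if g in set(meth.gene_ids)]
    samples = [s for s in expr.sample_ids if s in set(meth.sample_ids)]
    if not genes:
        raise ValueError("no shared gene ids between the two matrices")
    if not samples:
        raise ValueError("no shared sample ids between the two matrices")
    return (
        expr.subset_genes(genes).subset_samples(samples),
        meth.subset_genes(genes).subset_samples(samples),
    )


def inverse_regulation(
    expr_sel: SelectionResult, meth_sel: SelectionResult
) -> IntegrativeResult:
    """Intersect directional calls: expression-up with methylation-hypo and
    expression-down with methylation-hyper.

    For the methylation selection 'up' means hyper-methylated and 'down'
    hypo-methylated (direction of the group-mean beta difference).
    """
    expr_up = expr_sel.up_N | expr_sel.up_NN
    expr_down = expr_sel.down_N | expr_sel.down_NN
    hyper = meth_sel.up_N | meth_sel.up_NN
    hypo = meth_sel.down_N | meth_sel.down_NN
    universe = expr_sel.normal_genes | expr_sel.nonnormal_genes
    return IntegrativeResult(
        matched_genes=len(universe),
        matched_samples=0,
        up_and_hypo=expr_up & hypo,
        down_and_hyper=expr_down & hyper,
    )


def integrate(
    expr: LabeledMatrix, meth: LabeledMatrix, cfg: PipelineConfig
) -> IntegrativeResult:
    """Match, select on both matrices independently, and intersect."""
    expr_m, meth_m = match_datasets(expr, meth)
    expr_sel = select_genes(expr_m, cfg)
    meth_sel = select_genes(meth_m, cfg)
    res = inverse_regulation(expr_sel, meth_sel)
    res.matched_genes = len(expr_m.gene_ids)
    res.matched_samples = len(expr_m.sample_ids)
    return res
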