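"""Weighted majority-vote rule classification under repeated stratified CV.

Each repeat draws a fresh stratified k-fold split.  Per fold, homogeneous
maximal biclusters are mined on the training samples only, turned into
ranked, weighted rules, and every test point is classified by comparing the
summed weights of the satisfying rules per class; an exact tie goes to the
best-positioned satisfying rule, and a point satisfied by no rule receives
the class of the fallback rule (the rule satisfying the most test points of
the current fold).  Confusions are pooled per repeat and summarized as
sensitivity, specificity, accuracy and the Matthews correlation
coefficient.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .bimax import bimax_enumerate, filter_homogeneous
from .datatypes import ItemMatrix, PipelineConfig, Rule
from .rules import score_and_rank

__all__ = [
    "stratified_folds",
    "predict",
    "evaluate",
    "cross_validate",
    "anova_compare",
    "PredictionTrace",
    "ClassifierReport",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictionTrace:
    test_point: str
    satisfying_rule_ids: list[int]
    ws_experimental: float
    ws_control: float
    n_rules_experimental: int
    n_rules_control: int
    decision_path: str  # weighted_sum | tie_top_rule | fallback_rule
    predicted: str


@dataclass
class ClassifierReport:
    per_repeat: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def summarize(self) -> None:
        metrics = ("sensitivity", "specificity", "accuracy", "mcc")
        self.summary = {}
        for name in metrics:
            vals = np.array([r[name] for r in self.per_repeat], float)
            self.summary[f"mean_{name}"] = float(vals.mean())
            self.summary[f"sd_{name}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def stratified_folds(
    sample_ids: list[str],
    labels,
    k: int,
    seed: int,
    stratified: bool = True,
) -> list[list[str]]:
    """k disjoint test sets covering all samples, class-proportional per fold."""
    y = np.array([labels[s] for s in sample_ids])
    counts = pd.Series(y).value_counts()
    if stratified and (counts < k).any():
        small = counts[counts < k].index[0]
        raise ValueError(f"class {small!r} has fewer than {k} samples")
    if stratified:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
        return [
            [sample_ids[i] for i in test_idx]
            for _, test_idx in skf.split(np.zeros(len(y)), y)
        ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sample_ids))
    return [[sample_ids[i] for i in order[j::k]] for j in range(k)]


def predict(
    ts_row: pd.Series,
    rules: list[Rule],
    fallback: Rule | None,
    classes: tuple[str, str],
) -> PredictionTrace:
    """Weighted majority vote for a single item-row test point."""
    experimental, control = classes
    satisfying = []
    for r in rules:
        missing = r.antecedent - set(ts_row.index)
        if missing:
            raise KeyError(f"test point lacks item column(s): {sorted(missing)}")
        if all(ts_row[item] == 1 for item in r.antecedent):
            satisfying.append(r)
    ws_exp = sum(r.weight for r in satisfying if r.consequent == experimental)
    ws_ctl = sum(r.weight for r in satisfying if r.consequent == control)
    n_exp = sum(1 for r in satisfying if r.consequent == experimental)
    n_ctl = sum(1 for r in satisfying if r.consequent == control)
    if not satisfying:
        predicted = fallback.consequent if fallback is not None else control
        path = "fallback_rule"
    elif ws_exp == ws_ctl:
        top = min(satisfying, key=lambda r: r.position)
        predicted = top.consequent
        path = "tie_top_rule"
    else:
        predicted = experimental if ws_exp > ws_ctl else control
        path = "weighted_sum"
    return PredictionTrace(
        test_point=str(ts_row.name),
        satisfying_rule_ids=[r.id for r in satisfying],
        ws_experimental=ws_exp,
        ws_control=ws_ctl,
        n_rules_experimental=n_exp,
        n_rules_control=n_ctl,
        decision_path=path,
        predicted=predicted,
    )


def evaluate(predictions: list[str], truth: list[str], positive: str) -> dict:
    """Confusion counts and the four summary metrics.

    sensitivity = TP/(TP+FN); specificity = TN/(FP+TN);
    accuracy = (TP+TN)/total; MCC with the usual 0-denominator -> 0
    convention.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to evaluate")
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth differ in length")
    tp = sum(1 for p, t in zip(predictions, truth) if p == positive and t == positive)
    tn = sum(1 for p, t in zip(predictions, truth) if p != positive and t != positive)
    fp = sum(1 for p, t in zip(predictions, truth) if p == positive and t != positive)
    fn = sum(1 for p, t in zip(predictions, truth) if p != positive and t == positive)
    return _metrics_from_counts(tp, tn, fp, fn)


def _metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict:
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (fp + tn) if fp + tn else math.nan
    acc = (tp + tn) / (tp + fp + tn + fn)
    denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom > 0 else 0.0
    return {
        "TP": tp,
        "TN": tn,
        "FP": fp,
        "FN": fn,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "mcc": mcc,
    }


def _choose_fallback(rules: list[Rule], test_bits: pd.DataFrame) -> Rule | None:
    """The rule satisfying the most current-fold test points (tie: better
    position)."""
    if not rules:
        return None
    best, best_key = None, None
    for r in rules:
        sat = int(test_bits[list(r.antecedent)].all(axis=1).sum()) if r.antecedent else len(test_bits)
        key = (-sat, r.position)
        if best_key is None or key < best_key:
            best, best_key = r, key
    return best


def cross_validate(
    im: ItemMatrix,
    cfg: PipelineConfig,
    stratified: bool = True,
    collect_traces: bool = False,
) -> ClassifierReport:
    """Repeated stratified k-fold CV of the rule classifier.

    Rules are mined, ranked and weighted on each training fold alone;
    per-repeat metrics come from the fold-pooled confusion counts.
    """
    report = ClassifierReport(config={
        "folds": cfg.cv_folds,
        "repeats": cfg.cv_repeats,
        "min_items": cfg.min_items,
        "min_support": cfg.min_support,
        "weight_znorm": cfg.weight_znorm,
        "seed": cfg.seed,
        "stratified": stratified,
    })
    experimental = im.classes[0]
    samples = im.sample_ids
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.cv_repeats)
    traces: list[PredictionTrace] = []
    for rep in range(cfg.cv_repeats):
        folds = stratified_folds(
            samples, im.labels, cfg.cv_folds, int(seeds[rep]) % (2**31), stratified
        )
        tp = tn = fp = fn = 0
        for fold in folds:
            test_set = set(fold)
            train_ids = [s for s in samples if s not in test_set]
            train_im = im.subset_samples(train_ids)
            bics = bimax_enumerate(train_im, cfg.min_items, cfg.min_support)
            mfchois = filter_homogeneous(bics, train_im.labels)
            rules = score_and_rank(mfchois, train_im, znorm=cfg.weight_znorm)
            test_bits = im.bits.loc[fold]
            if not rules:
                train_majority = im.labels[train_ids].mode().iloc[0]
                logger.warning(
                    "repeat %d: training fold yielded zero rules; predicting "
                    "majority class %r", rep, train_majority
                )
                preds = [train_majority] * len(fold)
            else:
                fallback = _choose_fallback(rules, test_bits)
                preds = []
                for s in fold:
                    trace = predict(im.bits.loc[s], rules, fallback, im.classes)
                    preds.append(trace.predicted)
                    if collect_traces:
                        traces.append(trace)
            for s, p in zip(fold, preds):
                truth_pos = im.labels[s] == experimental
                pred_pos = p == experimental
                if truth_pos and pred_pos:
                    tp += 1
                elif truth_pos:
                    fn += 1
                elif pred_pos:
                    fp += 1
                else:
                    tn += 1
        report.per_repeat.append(_metrics_from_counts(tp, tn, fp, fn))
    report.summarize()
    if collect_traces:
        report.config["traces"] = traces
    return report


def anova_compare(*accuracy_series) -> tuple[float, float]:
    """One-way ANOVA across two or more accuracy series."""
    series = [np.asarray(s, float) for s in accuracy_series]
    if len(series) < 2 or any(len(s) < 2 for s in series):
        raise ValueError("need at least two series of length >= 2")
    flat = np.concatenate(series)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*series)
    if math.isnan(f):
        return 0.0, 1.0
    return float(f), float(p)
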