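"""Rule extraction, 24-measure scoring, fractional ranking and weighting.

Each homogeneous maximal bicluster yields one special rule: its item set as
the antecedent and its (single) sample class as the consequent.  Rules are
scored with 23 literature interestingness measures plus the number of
samples of the source bicluster, fractionally ranked per measure (larger
value = better = numerically smaller rank; ties get the mean of the ordinal
ranks they span; undefined values tie at the worst positions), aggregated
by the mean fractional rank, and mapped to voting weights
w_j = (p - (r_j - 1)) / p so the top rule always weighs 1 and consecutive
positions differ by exactly 1/p.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .datatypes import ContingencyCounts, ItemMatrix, MFCHOI, Rule

__all__ = [
    "MEASURE_NAMES",
    "extract_rule",
    "contingency",
    "compute_measures",
    "fractional_rank",
    "rank_rules",
    "assign_weights",
    "gene_frequency",
    "score_and_rank",
]

MEASURE_NAMES = (
    "support",
    "confidence",
    "coverage",
    "prevalence",
    "sensitivity",
    "specificity",
    "accuracy",
    "lift",
    "leverage",
    "added_value",
    "relative_risk",
    "jaccard",
    "yules_q",
    "klosgen",
    "laplace",
    "gini_gain",
    "two_way_support",
    "phi",
    "cosine",
    "least_contradiction",
    "zhang",
    "piatetsky_shapiro",
    "kappa",
    "satisfied_conditions",
)

UNDEFINED = math.nan  # sentinel: a measure that cannot be evaluated


def extract_rule(m: MFCHOI, rule_id: int = 0) -> Rule:
    """Special rule A => C from one homogeneous maximal bicluster."""
    return Rule(
        id=rule_id,
        antecedent=m.bicluster.G,
        consequent=m.class_label,
        source_samples=m.bicluster.S,
    )


def contingency(r: Rule, im: ItemMatrix) -> ContingencyCounts:
    """2x2 counts of the rule over the item matrix.

    A sample satisfies the antecedent when every antecedent item column is
    1 for it; it satisfies the consequent when its class label equals the
    rule's consequent.
    """
    unknown = r.antecedent - set(im.item_names)
    if unknown:
        raise KeyError(f"unknown item(s) in antecedent: {sorted(unknown)}")
    n = im.bits.shape[0]
    if r.antecedent:
        sat_A = im.bits[list(r.antecedent)].all(axis=1)
    else:
        sat_A = np.ones(n, dtype=bool)
    is_C = (im.labels == r.consequent).to_numpy()
    return ContingencyCounts(
        n=n,
        n_A=int(np.sum(sat_A)),
        n_C=int(np.sum(is_C)),
        n_AC=int(np.sum(np.asarray(sat_A) & is_C)),
    )


def compute_measures(r: Rule, c: ContingencyCounts) -> dict[str, float]:
    """The 24 interestingness measures of a rule from its 2x2 counts.

    Probabilities are empirical fractions of the n samples.  A measure with
    a zero denominator or a log of zero is reported as the 'undefined'
    sentinel (NaN), which the ranking stage places at the worst positions.
    """
    if c.n <= 0:
        raise ValueError("contingency must cover at least one sample")
    n = float(c.n)
    a = c.n_AC                      # A and C
    b = c.n_A - c.n_AC              # A and not C
    cc = c.n_C - c.n_AC             # not A and C
    d = c.n - c.n_A - c.n_C + c.n_AC  # neither
    pA = c.n_A / n
    pC = c.n_C / n
    pAC = c.n_AC / n
    pnA = 1.0 - pA
    pnC = 1.0 - pC
    pAnC = b / n
    pnAnC = d / n

    m: dict[str, float] = {}
    m["support"] = pAC
    conf = pAC / pA if pA > 0 else UNDEFINED
    m["confidence"] = conf
    m["coverage"] = pA
    m["prevalence"] = pC
    m["sensitivity"] = pAC / pC if pC > 0 else UNDEFINED
    m["specificity"] = pnAnC / pnC if pnC > 0 else UNDEFINED
    m["accuracy"] = pAC + pnAnC
    m["lift"] = conf / pC if (pC > 0 and not math.isnan(conf)) else UNDEFINED
    m["leverage"] = conf - pA * pC if not math.isnan(conf) else UNDEFINED
    m["added_value"] = conf - pC if not math.isnan(conf) else UNDEFINED
    if pA > 0 and pnA > 0 and cc > 0:
        m["relative_risk"] = (a / (a + b)) / (cc / (cc + d))
    else:
        m["relative_risk"] = UNDEFINED
    denom = pA + pC - pAC
    m["jaccard"] = pAC / denom if denom > 0 else UNDEFINED
    ad, bc = a * d, b * cc
    m["yules_q"] = (ad - bc) / (ad + bc) if (ad + bc) > 0 else UNDEFINED
    m["klosgen"] = (
        math.sqrt(pAC) * (conf - pC) if not math.isnan(conf) else UNDEFINED
    )
    m["laplace"] = (c.n_AC + 1) / (c.n_A + 2)
    if pA > 0 and pnA > 0:
        gini = (
            pA * ((a / (a + b)) ** 2 + (b / (a + b)) ** 2)
            + pnA * ((cc / (cc + d)) ** 2 + (d / (cc + d)) ** 2)
            - pC**2
            - pnC**2
        )
        m["gini_gain"] = gini
    else:
        m["gini_gain"] = UNDEFINED
    if pAC > 0 and pA > 0 and pC > 0:
        m["two_way_support"] = pAC * math.log2(pAC / (pA * pC))
    else:
        m["two_way_support"] = UNDEFINED
    denom = pA * pC * pnA * pnC
    m["phi"] = (pAC - pA * pC) / math.sqrt(denom) if denom > 0 else UNDEFINED
    m["cosine"] = pAC / math.sqrt(pA * pC) if pA * pC > 0 else UNDEFINED
    m["least_contradiction"] = (pAC - pAnC) / pC if pC > 0 else UNDEFINED
    denom = max(pAC * pnC, pC * pAnC)
    m["zhang"] = (pAC - pA * pC) / denom if denom > 0 else UNDEFINED
    m["piatetsky_shapiro"] = pAC - pA * pC
    denom = 1.0 - pA * pC - pnA * pnC
    if denom > 0:
        m["kappa"] = (pAC + pnAnC - pA * pC - pnA * pnC) / denom
    else:
        m["kappa"] = UNDEFINED
    m["satisfied_conditions"] = float(len(r.source_samples))
    assert tuple(m) == MEASURE_NAMES
    return m


def fractional_rank(values, larger_is_better: bool = True) -> np.ndarray:
    """Fractional (mean-of-ordinals) ranks; ties share the mean of the
    ordinal ranks they would span.

    With ``larger_is_better`` (the sense used for the interestingness
    measures) the largest value receives rank 1; with it off the ranking is
    the classic ascending illustration where {1, 2, 2} -> {1, 2.5, 2.5}.
    NaN marks an undefined value; all undefined entries tie at the mean of
    the worst positions in either sense.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("need at least one value")
    ranks = np.empty(v.shape, float)
    defined = ~np.isnan(v)
    n_def = int(defined.sum())
    if n_def:
        key = -v[defined] if larger_is_better else v[defined]
        ranks[defined] = stats.rankdata(key, method="average")
    n_undef = v.size - n_def
    if n_undef:
        worst = (n_def + 1 + v.size) / 2.0  # mean of positions n_def+1 .. n
        ranks[~defined] = worst
    return ranks


def rank_rules(rules: list[Rule]) -> list[Rule]:
    """Aggregate the 24 fractional rankings and order the rules.

    final_rank is the mean of the rule's 24 fractional ranks; rules are
    sorted ascending by final_rank with ties broken by smaller rule id, and
    1-based positions assigned.  Input objects are not mutated.
    """
    if not rules:
        return []
    rules = [r.copy() for r in rules]
    matrix = np.array(
        [[r.measures[name] for r in rules] for name in MEASURE_NAMES], float
    )
    for i, name in enumerate(MEASURE_NAMES):
        fr = fractional_rank(matrix[i])
        for r, rank in zip(rules, fr):
            r.fractional_ranks[name] = float(rank)
    for r in rules:
        r.final_rank = float(np.mean([r.fractional_ranks[n] for n in MEASURE_NAMES]))
    rules.sort(key=lambda r: (r.final_rank, r.id))
    for pos, r in enumerate(rules, start=1):
        r.position = pos
    return rules


def assign_weights(rules: list[Rule], znorm: bool = False) -> list[Rule]:
    """Affine position-to-weight map w_j = (p - (r_j - 1)) / p.

    Position 1 gets weight 1, position p gets 1/p, and consecutive
    positions differ by exactly 1/p.  With ``znorm`` the weight vector is
    additionally zero-mean normalized (off by default: zero-mean weights
    make half the votes negative, which contradicts the direct weighted-sum
    voting mechanism; the flag preserves the printed option).
    """
    p = len(rules)
    if p == 0:
        return []
    for r in rules:
        if not (1 <= r.position <= p):
            raise ValueError("positions must be assigned before weighting")
        r.weight = (p - (r.position - 1)) / p
    if znorm:
        w = np.array([r.weight for r in rules], float)
        sd = w.std(ddof=1) if p > 1 else 0.0
        if sd == 0:
            w = w - w.mean()
        else:
            w = (w - w.mean()) / sd
        for r, wi in zip(rules, w):
            r.weight = float(wi)
    return rules


def score_and_rank(
    mfchois: list[MFCHOI], im: ItemMatrix, znorm: bool = False
) -> list[Rule]:
    """Convenience: extract, score, rank and weight rules from MFCHOIs."""
    rules = []
    for i, m in enumerate(mfchois, start=1):
        r = extract_rule(m, rule_id=i)
        r.measures = compute_measures(r, contingency(r, im))
        rules.append(r)
    ranked = rank_rules(rules)
    return assign_weights(ranked, znorm=znorm)


def gene_frequency(rules: list[Rule], class_label: str) -> list[tuple[str, int]]:
    """Signed-item occurrence counts over the rules of one class.

    Sorted by descending count, ties lexicographic; items absent from the
    class's rules are omitted.
    """
    counts: dict[str, int] = {}
    for r in rules:
        if r.consequent != class_label:
            continue
        for item in r.antecedent:
            counts[item] = counts.get(item, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
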