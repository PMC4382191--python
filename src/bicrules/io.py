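"""Delimited-text I/O for matrices, item matrices, rules and reports.

Matrices are genes-in-rows delimited text with a header row of sample ids;
the delimiter follows the extension (.tsv tab, .csv comma, anything else
tab).  Labels are two-column files mapping every sample id to one of two
class names.  Rules are written as a TSV (one row per rule with all 24
measures, the final rank and the weight) plus a JSON sidecar carrying full
provenance so a rule file round-trips losslessly.
"""
from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ItemMatrix, LabeledMatrix, LoadError, Rule
from .rules import MEASURE_NAMES

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_item_matrix",
    "read_item_matrix",
    "write_rules",
    "read_rules",
]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_labels(labels_path: str | Path) -> pd.Series:
    df = pd.read_csv(labels_path, sep=_sep_for(labels_path), header=None, dtype=str,
                     comment="#")
    if df.shape[1] < 2:
        raise LoadError("labels file needs two columns: sample_id, class")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class")
    if ser.index.duplicated().any():
        dup = ser.index[ser.index.duplicated()][0]
        raise LoadError(f"duplicate sample id in labels file: {dup!r}")
    return ser


def read_matrix(
    path: str | Path,
    labels_path: str | Path,
    positive_class: str | None = None,
) -> LabeledMatrix:
    """Load a gene x sample matrix and its sample labels.

    ``positive_class`` names the experimental class; with None, the class
    of the first sample listed in the labels file is taken as experimental.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise LoadError(f"non-numeric cell in matrix {path}: {exc}") from exc
    labels_all = read_labels(labels_path)
    missing = [s for s in values.columns if s not in labels_all.index]
    if missing:
        raise LoadError(f"sample {missing[0]!r} missing from labels file")
    labels = labels_all[list(values.columns)]
    class_names = list(dict.fromkeys(labels_all.values))  # file order
    if len(set(labels.unique())) != 2:
        raise LoadError(
            f"exactly two classes required, found {sorted(set(labels.unique()))}"
        )
    if len(class_names) != 2:
        raise LoadError(f"exactly two classes required, found {class_names}")
    if positive_class is None:
        positive_class = class_names[0]
    if positive_class not in class_names:
        raise LoadError(f"positive class {positive_class!r} not in labels")
    negative = next(c for c in class_names if c != positive_class)
    return LabeledMatrix(values, labels, (positive_class, negative))


def write_matrix(m: LabeledMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep=_sep_for(path))


def write_labels(m: LabeledMatrix, path: str | Path) -> None:
    sep = _sep_for(path)
    # experimental class first so the positive class round-trips
    ordered = sorted(m.sample_ids, key=lambda s: m.labels[s] != m.experimental)
    with open(path, "w") as fh:
        for s in ordered:
            fh.write(f"{s}{sep}{m.labels[s]}\n")


def write_item_matrix(im: ItemMatrix, path: str | Path) -> None:
    """Item-matrix TSV: item columns plus a final class column."""
    out = im.bits.copy()
    out["class"] = [im.labels[s] for s in im.sample_ids]
    out.to_csv(path, sep=_sep_for(path))


def read_item_matrix(path: str | Path, positive_class: str | None = None) -> ItemMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if "class" not in df.columns:
        raise LoadError("item matrix file lacks the final 'class' column")
    labels = df.pop("class").astype(str)
    items = []
    for col in df.columns:
        if not col or col[-1] not in "+-":
            raise LoadError(f"item column {col!r} lacks a +/- sign suffix")
        items.append((col[:-1], col[-1]))
    class_names = list(dict.fromkeys(labels.values))
    if len(class_names) != 2:
        raise LoadError(f"exactly two classes required, found {class_names}")
    if positive_class is None:
        positive_class = class_names[0]
    negative = next(c for c in class_names if c != positive_class)
    return ItemMatrix(df.astype(int), items, labels, (positive_class, negative))


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

def write_rules(rules: list[Rule], path: str | Path, provenance: dict | None = None) -> None:
    """Rules TSV plus a JSON sidecar (same path + '.json').

    The TSV carries one row per rule: id, antecedent items, consequent
    class, the 24 measure columns, the final rank and the weight.  The
    sidecar holds everything needed to reconstruct the Rule objects
    exactly, plus caller-supplied provenance (seed, config, sample sets).
    """
    path = Path(path)
    rows = []
    for r in rules:
        row = {
            "id": r.id,
            "antecedent": ",".join(sorted(r.antecedent)),
            "consequent": r.consequent,
        }
        for name in MEASURE_NAMES:
            row[name] = r.measures.get(name, math.nan)
        row["final_rank"] = r.final_rank
        row["position"] = r.position
        row["weight"] = r.weight
        rows.append(row)
    cols = ["id", "antecedent", "consequent", *MEASURE_NAMES, "final_rank", "position", "weight"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    def _clean(x: float) -> float | None:
        return None if isinstance(x, float) and math.isnan(x) else x

    sidecar = {
        "provenance": provenance or {},
        "rules": [
            {
                "id": r.id,
                "antecedent": sorted(r.antecedent),
                "consequent": r.consequent,
                "source_samples": sorted(r.source_samples),
                "measures": {k: _clean(v) for k, v in r.measures.items()},
                "fractional_ranks": {k: _clean(v) for k, v in r.fractional_ranks.items()},
                "final_rank": _clean(r.final_rank),
                "position": r.position,
                "weight": _clean(r.weight),
            }
            for r in rules
        ],
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_rules(path: str | Path) -> list[Rule]:
    """Reconstruct Rule objects from the JSON sidecar of ``write_rules``."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        data = json.load(fh)

    def _num(x) -> float:
        return math.nan if x is None else float(x)

    out = []
    for d in data["rules"]:
        out.append(
            Rule(
                id=int(d["id"]),
                antecedent=frozenset(d["antecedent"]),
                consequent=d["consequent"],
                source_samples=frozenset(d["source_samples"]),
                measures={k: _num(v) for k, v in d["measures"].items()},
                fractional_ranks={k: _num(v) for k, v in d["fractional_ranks"].items()},
                final_rank=_num(d["final_rank"]),
                position=int(d["position"]),
                weight=_num(d["weight"]),
            )
        )
    return out
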