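"""Metric machinery: flat, hierarchical (set-based and count-preserving),
and weak hierarchical confusion-matrix error rates.

Three views of multi-label coding quality are provided:

* **leaf-only / flat** — micro- and macro-averaged precision, recall and F1
  over the raw label sets, restricted to a codeset;
* **hierarchical** — gold and prediction sets are extended with their
  ancestor nodes before counting.  In *set-based* mode an ancestor is
  present iff at least one descendant is present; in *count-preserving*
  mode (CoPHE) an ancestor carries the number of its present descendant
  leaves, so over- and under-prediction within a code family is penalized;
* **WHCM** — weak hierarchical confusion matrices classify each missed gold
  label as a *within-family* (IF) error when the prediction set contains at
  least one false positive from the same family, else an *out-of-family*
  (OOF) error.  Rates are macro-averaged percentages over gold instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .hierarchy import CodeId, Hierarchy, family_of

logger = logging.getLogger(__name__)

LabelSets = Sequence[Iterable[CodeId]]


@dataclass(frozen=True)
class MetricsReport:
    codeset_name: str
    variant: str  # leaf-only | set-based | cophe
    micro_p: float
    micro_r: float
    micro_f1: float
    macro_p: float
    macro_r: float
    macro_f1: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "codeset": self.codeset_name,
            "variant": self.variant,
            "micro_p": self.micro_p,
            "micro_r": self.micro_r,
            "micro_f1": self.micro_f1,
            "macro_p": self.macro_p,
            "macro_r": self.macro_r,
            "macro_f1": self.macro_f1,
        }


@dataclass(frozen=True)
class WHCMReport:
    codeset_name: str
    oof_rate: float  # macro-averaged %, over codeset labels with >=1 gold instance
    if_rate: float
    tp_rate: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "codeset": self.codeset_name,
            "oof_rate": self.oof_rate,
            "if_rate": self.if_rate,
            "tp_rate": self.tp_rate,
        }


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def flat_metrics(
    gold: LabelSets,
    pred: LabelSets,
    codeset: Iterable[CodeId],
    codeset_name: str = "codeset",
) -> MetricsReport:
    """Micro/macro P, R, F1 over label sets restricted to ``codeset``.

    Micro pools true/false positives and negatives over all (document,
    label) pairs; macro averages per-label scores with equal weight,
    counting codeset labels with no gold and no predicted instances as
    zeros (fixed-label-space convention).
    """
    if len(gold) != len(pred):
        raise ValueError("gold and pred must cover the same documents")
    labels = sorted(set(codeset))
    if not labels:
        raise ValueError("empty codeset")
    index = {c: j for j, c in enumerate(labels)}
    y_true = np.zeros((len(gold), len(labels)), dtype=np.int8)
    y_pred = np.zeros_like(y_true)
    for i, (g, p) in enumerate(zip(gold, pred)):
        for c in g:
            if c in index:
                y_true[i, index[c]] = 1
        for c in p:
            if c in index:
                y_pred[i, index[c]] = 1
    tp = (y_true & y_pred).sum(axis=0).astype(float)
    fp = (~y_true.astype(bool) & y_pred.astype(bool)).sum(axis=0).astype(float)
    fn = (y_true.astype(bool) & ~y_pred.astype(bool)).sum(axis=0).astype(float)

    def _prf(tp_, fp_, fn_):
        with np.errstate(invalid="ignore"):
            p = np.where(tp_ + fp_ > 0, tp_ / np.maximum(tp_ + fp_, 1e-300), 0.0)
            r = np.where(tp_ + fn_ > 0, tp_ / np.maximum(tp_ + fn_, 1e-300), 0.0)
            f = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-300), 0.0)
        return p, r, f

    mi_p, mi_r, mi_f = _prf(tp.sum(), fp.sum(), fn.sum())
    pl_p, pl_r, pl_f = _prf(tp, fp, fn)
    return MetricsReport(
        codeset_name, "leaf-only",
        float(mi_p), float(mi_r), float(mi_f),
        float(pl_p.mean()), float(pl_r.mean()), float(pl_f.mean()),
    )


def extend_with_ancestors(
    labels: Iterable[CodeId],
    hierarchy: Hierarchy,
    mode: str = "counts",
) -> dict[str, int]:
    """Node-count vector for a label set extended with its ancestors.

    ``mode="set"``: every node present gets count 1.  ``mode="counts"``
    (CoPHE): each ancestor carries the number of its descendant leaves in
    the label set; leaves carry 1.
    """
    if mode not in ("set", "counts"):
        raise ValueError(f"unknown mode {mode!r}")
    vector: dict[str, int] = {}
    for code in labels:
        vector[code] = 1
        for node in hierarchy.ancestors_of(code):
            vector[node] = vector.get(node, 0) + 1
    if mode == "set":
        vector = {node: 1 for node in vector}
    return vector


def hierarchical_metrics(
    gold: LabelSets,
    pred: LabelSets,
    hierarchy: Hierarchy,
    variant: str = "cophe",
    codeset_name: str = "codeset",
    average: str = "micro",
) -> MetricsReport:
    """P/R/F1 after ancestor extension.

    ``variant`` is ``"set_based"`` or ``"cophe"``.  Per node, with gold
    count g and predicted count p: TP = min(g, p), FP = max(p - g, 0),
    FN = max(g - p, 0).  The default ``average="micro"`` pools counts over
    (document, node) pairs and reports one P/R/F1 triple (mirrored into
    the macro fields); ``average="macro"`` additionally averages per-node
    scores with equal node weight into the macro fields.
    """
    if variant not in ("set_based", "cophe"):
        raise ValueError(f"unknown variant {variant!r}")
    if average not in ("micro", "macro"):
        raise ValueError(f"unknown average {average!r}")
    mode = "set" if variant == "set_based" else "counts"
    if len(gold) != len(pred):
        raise ValueError("gold and pred must cover the same documents")
    per_node: dict[str, list[int]] = {}
    for g_labels, p_labels in zip(gold, pred):
        g_vec = extend_with_ancestors(g_labels, hierarchy, mode)
        p_vec = extend_with_ancestors(p_labels, hierarchy, mode)
        for node in set(g_vec) | set(p_vec):
            g, p = g_vec.get(node, 0), p_vec.get(node, 0)
            cell = per_node.setdefault(node, [0, 0, 0])
            cell[0] += min(g, p)
            cell[1] += max(p - g, 0)
            cell[2] += max(g - p, 0)
    tp = sum(c[0] for c in per_node.values())
    fp = sum(c[1] for c in per_node.values())
    fn = sum(c[2] for c in per_node.values())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = _f1(precision, recall)
    if average == "macro" and per_node:
        ps, rs, fs = [], [], []
        for c in per_node.values():
            p = c[0] / (c[0] + c[1]) if c[0] + c[1] else 0.0
            r = c[0] / (c[0] + c[2]) if c[0] + c[2] else 0.0
            ps.append(p)
            rs.append(r)
            fs.append(_f1(p, r))
        ma_p, ma_r, ma_f = (
            float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))
        )
    else:
        ma_p, ma_r, ma_f = precision, recall, f1
    name = "set-based" if variant == "set_based" else "cophe"
    return MetricsReport(
        codeset_name, name, precision, recall, f1, ma_p, ma_r, ma_f
    )


def whcm_rates(
    gold: LabelSets,
    pred: LabelSets,
    codeset: Iterable[CodeId],
    hierarchy: Hierarchy | None = None,
    codeset_name: str = "codeset",
) -> WHCMReport:
    """Weak hierarchical confusion-matrix error rates over ``codeset``.

    Per document and per codeset label with a gold instance: the instance
    is a TP if predicted; otherwise a within-family (IF) error if the
    prediction set contains at least one false positive from the same
    family ("weak" matching: existence, not one-to-one assignment), else an
    out-of-family (OOF) error.  Per-label percentages are macro-averaged
    over codeset labels with at least one gold instance.
    """
    if len(gold) != len(pred):
        raise ValueError("gold and pred must cover the same documents")
    codeset = set(codeset)
    counts: dict[CodeId, np.ndarray] = {}  # label -> [tp, if, oof]
    for g_labels, p_labels in zip(gold, pred):
        g_set, p_set = set(g_labels), set(p_labels)
        false_pos_families = {family_of(c) for c in p_set - g_set}
        for label in g_set & codeset:
            cell = counts.setdefault(label, np.zeros(3, dtype=np.int64))
            if label in p_set:
                cell[0] += 1
            elif family_of(label) in false_pos_families:
                cell[1] += 1
            else:
                cell[2] += 1
    skipped = codeset - set(counts)
    if skipped:
        logger.debug("WHCM: %d codeset labels had no gold instances", len(skipped))
    if not counts:
        raise ValueError("no codeset label has a gold instance")
    rates = np.array([cell / cell.sum() for cell in counts.values()])
    tp_rate, if_rate, oof_rate = (100.0 * rates.mean(axis=0)).tolist()
    return WHCMReport(codeset_name, oof_rate, if_rate, tp_rate)
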