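"""Rater-agreement statistics for the clinician-style document review.

Design: a fixed panel of raters scores each document on seven named
criteria with ordinal scores 1-5.  Agreement per criterion is summarized
with Fleiss' kappa (treating the five score levels as nominal categories)
plus the mean score, separately for real and synthetic documents.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .errors import DegenerateAgreementError

logger = logging.getLogger(__name__)

#: The seven review criteria.
METRICS = (
    "correctness_nonlow",
    "correctness_low",
    "informativeness_nonlow",
    "informativeness_low",
    "authenticity_patient",
    "authenticity_scenario",
    "acceptability",
)

SCORE_LEVELS = (1, 2, 3, 4, 5)
ITEM_CLASSES = ("real", "synthetic")


@dataclass
class RatingTable:
    """Long-format scores: one row per (item, rater, metric).

    Columns: ``item_id``, ``item_class`` (real|synthetic), ``rater_id``,
    ``metric``, ``score`` (integer in [1, 5]).  The table must be complete:
    every rater scores every item on every metric.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"item_id", "item_class", "rater_id", "metric", "score"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"rating table needs columns {sorted(required)}")
        scores = self.frame["score"]
        if not scores.between(1, 5).all():
            raise ValueError("scores must lie in [1, 5]")
        bad_class = set(self.frame["item_class"]) - set(ITEM_CLASSES)
        if bad_class:
            raise ValueError(f"unknown item classes: {sorted(bad_class)}")
        cells = self.frame.groupby(["metric", "item_id"])["rater_id"].nunique()
        if cells.nunique() > 1:
            raise ValueError("incomplete table: unequal raters per item")

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        return cls(pd.read_csv(path, dtype={"score": int}))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def fleiss_kappa(
    assignments: list[list],
    categories: list | None = None,
    weights: str | None = None,
) -> float:
    """Fleiss' kappa for item x rater category assignments.

    ``assignments`` is one list of category labels per item (equal raters
    per item).  Standard formula: kappa = (Pbar - Pbar_e) / (1 - Pbar_e)
    over the given (or observed) category list.  ``weights="linear"``
    computes the ordinal generalization in which a rater pair disagreeing
    by adjacent categories counts 1 - |j - k| / (K - 1) toward agreement;
    the default (None) is the standard nominal statistic.

    Raises
    ------
    DegenerateAgreementError
        When chance agreement is 1 (all raters always in one category).
    """
    if len(assignments) < 2:
        raise ValueError("need at least 2 items")
    n_raters = {len(item) for item in assignments}
    if len(n_raters) != 1 or n_raters == {0} or next(iter(n_raters)) < 2:
        raise ValueError("need an equal number (>=2) of raters per item")
    if categories is None:
        categories = sorted({c for item in assignments for c in item})
    index = {c: j for j, c in enumerate(categories)}
    table = np.zeros((len(assignments), len(categories)), dtype=np.int64)
    for i, item in enumerate(assignments):
        for cat in item:
            table[i, index[cat]] += 1
    marginals = table.sum(axis=0) / table.sum()
    if weights is None:
        if np.isclose((marginals ** 2).sum(), 1.0):
            raise DegenerateAgreementError(
                "all raters in a single category; kappa undefined"
            )
        return float(_sm_fleiss_kappa(table, method="fleiss"))
    if weights != "linear":
        raise ValueError(f"unknown weights {weights!r}")
    k = len(categories)
    j = np.arange(k)
    w = 1.0 - np.abs(j[:, None] - j[None, :]) / max(k - 1, 1)
    n = table.sum(axis=1)[0]
    # observed: weighted agreeing pairs per item over n(n-1) ordered pairs
    pairs = table[:, :, None] * table[:, None, :]
    pairs[:, j, j] = table * (table - 1)
    p_obs = float((pairs * w).sum(axis=(1, 2)).mean() / (n * (n - 1)))
    p_exp = float(marginals @ w @ marginals)
    if np.isclose(p_exp, 1.0):
        raise DegenerateAgreementError(
            "weighted chance agreement is 1; kappa undefined"
        )
    return (p_obs - p_exp) / (1.0 - p_exp)


@dataclass(frozen=True)
class AgreementReport:
    """Per metric and per item class: kappa and mean score (NaN kappa marks
    a degenerate metric, e.g. unanimous single-category scoring)."""

    frame: pd.DataFrame  # rows: metric; columns: kappa_real, mu_real, ...

    def as_dict(self) -> dict:
        return {
            metric: {k: (None if isinstance(v, float) and math.isnan(v) else v)
                     for k, v in row.items()}
            for metric, row in self.frame.to_dict(orient="index").items()
        }

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="metric")


def agreement_report(table: RatingTable) -> AgreementReport:
    """Kappa and mean score per metric, stratified by real/synthetic items.

    A degenerate kappa (chance agreement 1) is recorded as NaN without
    aborting the remaining metrics.
    """
    rows = {}
    for metric in sorted(table.frame["metric"].unique()):
        row = {}
        sub_metric = table.frame[table.frame["metric"] == metric]
        for item_class in ITEM_CLASSES:
            sub = sub_metric[sub_metric["item_class"] == item_class]
            if sub.empty:
                row[f"kappa_{item_class}"] = float("nan")
                row[f"mu_{item_class}"] = float("nan")
                continue
            assignments = [
                group["score"].tolist() for _, group in sub.groupby("item_id")
            ]
            try:
                kappa = fleiss_kappa(assignments, categories=list(SCORE_LEVELS))
            except DegenerateAgreementError:
                logger.info("degenerate kappa for %s/%s", metric, item_class)
                kappa = float("nan")
            row[f"kappa_{item_class}"] = kappa
            row[f"mu_{item_class}"] = float(sub["score"].mean())
        rows[metric] = row
    return AgreementReport(pd.DataFrame.from_dict(rows, orient="index"))
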