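"""Ranking-based evaluation: RFPP, accuracy order, NCPD and summaries.

For one dimer the pairs are ranked by descending predicted interface
probability (stable sort: ties keep the original pair order).  RFPP is the
1-based rank of the first true interface pair in that ranking; dividing by
the dimer's total pair count TNRP gives the accuracy order, reported in
per-mille so that values are comparable across dimers of very different
sizes.  NCPD(m per-mille) counts the dimers whose accuracy order is at most
m per-mille.  A dimer without any positive label gets the sentinel
RFPP = TNRP + 1 with an explicit flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "RankingReport",
    "rank_pairs",
    "accuracy_order",
    "ncpd",
    "rfpp_percentile",
    "summarize_model",
    "balanced_accuracy",
    "accuracy_order_table",
]


@dataclass
class RankingReport:
    dimer_id: str
    ranking: np.ndarray            # pair indices by descending score
    rfpp: int                      # 1-based; tnrp + 1 when no positive exists
    tnrp: int
    accuracy_order_permille: Optional[float]
    labels: np.ndarray
    no_positive: bool = False


def rank_pairs(scores, labels, tnrp: Optional[int] = None,
               dimer_id: str = "dimer") -> RankingReport:
    """Rank pairs by descending score and locate the first true positive.

    ``tnrp`` defaults to the number of scored pairs but can be passed
    explicitly when the scored list is a reduced subset of a larger
    candidate universe (accuracy order then uses the full count).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length vectors")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores contain non-finite values")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary")
    tnrp = int(tnrp) if tnrp is not None else len(scores)
    order = np.argsort(-scores, kind="stable")
    ranked_labels = labels[order]
    hits = np.flatnonzero(ranked_labels == 1)
    if hits.size:
        rfpp = int(hits[0]) + 1
        acc = accuracy_order(rfpp, tnrp)
        no_pos = False
    else:
        rfpp = tnrp + 1
        acc = None
        no_pos = True
    return RankingReport(dimer_id=dimer_id, ranking=order, rfpp=rfpp, tnrp=tnrp,
                         accuracy_order_permille=acc,
                         labels=labels.astype(int), no_positive=no_pos)


def accuracy_order(rfpp: int, tnrp: int) -> float:
    """1000 * RFPP / TNRP in per-mille, rounded to 3 decimals for reporting."""
    if tnrp <= 0:
        raise ValidationError("TNRP must be positive")
    if not (1 <= rfpp <= tnrp):
        raise ValidationError(f"RFPP={rfpp} outside [1, TNRP={tnrp}]")
    return round(1000.0 * rfpp / tnrp, 3)


def ncpd(accuracy_orders: Sequence[float], threshold_permille: float) -> int:
    """Number of correctly predicted dimers: how many accuracy orders (in
    per-mille) are at most the threshold."""
    if threshold_permille <= 0:
        raise ValidationError("threshold must be positive")
    vals = list(accuracy_orders)
    if not vals:
        warnings.warn("NCPD of an empty dimer list is 0", stacklevel=2)
        return 0
    return int(sum(1 for v in vals if v <= threshold_permille))


def rfpp_percentile(per_dimer_rfpp: Sequence[int], p: float) -> int:
    """Order statistic of the per-dimer RFPPs at fraction ``p``.

    Convention: sort ascending and take the 1-based index
    round-half-down(p * n), clamped to [1, n].  With this convention the
    published per-dimer RFPPs of the reference model reproduce all five of
    its printed quantiles (10/25/50/75/90%).
    """
    vals = sorted(per_dimer_rfpp)
    if not vals:
        raise ValidationError("empty RFPP list")
    if not (0 < p <= 1):
        raise ValidationError(f"p={p} must lie in (0, 1]")
    idx = math.ceil(p * len(vals) - 0.5)      # round half down
    idx = min(max(idx, 1), len(vals))
    return vals[idx - 1]


def summarize_model(per_dimer_accuracy_orders: Sequence[float],
                    dimer_ids: Optional[Sequence[str]] = None,
                    model_name: str = "model") -> tuple[float, pd.DataFrame]:
    """Arithmetic mean of per-dimer accuracy orders (as fractions) plus a
    one-column table with the per-dimer values and a final mean row."""
    vals = np.asarray(list(per_dimer_accuracy_orders), dtype=float)
    if vals.size == 0:
        raise ValidationError("no accuracy orders to summarize")
    mean = float(vals.mean())
    ids = list(dimer_ids) if dimer_ids is not None else [
        f"dimer{i}" for i in range(vals.size)]
    table = pd.DataFrame({model_name: list(vals) + [mean]},
                         index=ids + ["mean"])
    return mean, table


def accuracy_order_table(per_model: dict, dimer_ids: Sequence[str]) -> pd.DataFrame:
    """Combine several models' per-dimer accuracy orders into one table with
    dimers as rows, models as columns and a mean row last."""
    cols = {}
    for name, vals in per_model.items():
        vals = list(vals)
        if len(vals) != len(dimer_ids):
            raise ValidationError(f"model {name!r} has {len(vals)} values for "
                                  f"{len(dimer_ids)} dimers")
        cols[name] = vals + [float(np.mean(vals))]
    return pd.DataFrame(cols, index=list(dimer_ids) + ["mean"])


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of sensitivity and specificity for binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors must have equal length")
    rates = []
    for cls in (0, 1):
        mask = y_true == cls
        if mask.any():
            rates.append(float((y_pred[mask] == cls).mean()))
    return float(np.mean(rates))
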