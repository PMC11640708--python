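"""Group fairness metrics for binary classifiers.

All metrics follow the unprivileged-minus-privileged sign convention
(differences) and unprivileged-over-privileged (ratios).  Rates that are
undefined for a group (no positives for a TPR, no negatives for an FPR)
raise :class:`UndefinedRateError` naming the group rather than returning a
silent zero.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "FairnessReport",
    "GroupRates",
    "LabeledPredictions",
    "UndefinedRateError",
    "average_odds_difference",
    "balanced_accuracy",
    "compute_report",
    "demographic_parity_difference",
    "disparate_impact",
    "equal_opportunity_difference",
    "group_confusion",
    "mean_outcome_difference",
    "theil_index",
]


class UndefinedRateError(ValueError):
    """A confusion rate is undefined (degenerate class composition)."""


@dataclass(frozen=True)
class LabeledPredictions:
    """Per-subject labels, scores, predictions and sensitive attribute.

    Attributes
    ----------
    y_true:
        Observed binary outcome.
    y_score:
        Predicted probability of the positive class, in [0, 1].
    y_pred:
        Predicted binary label.
    group:
        Sensitive-attribute value per subject (any hashable code).
    """

    y_true: np.ndarray
    y_score: np.ndarray
    y_pred: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y_true", np.asarray(self.y_true))
        object.__setattr__(self, "y_score", np.asarray(self.y_score, dtype=float))
        object.__setattr__(self, "y_pred", np.asarray(self.y_pred))
        object.__setattr__(self, "group", np.asarray(self.group))
        n = len(self.y_true)
        if not (len(self.y_score) == len(self.y_pred) == len(self.group) == n):
            raise ValueError("all vectors must have equal length")
        for name in ("y_true", "y_pred"):
            vals = np.unique(getattr(self, name))
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError(f"{name} must be binary 0/1, got values {vals}")
        if n and (self.y_score.min() < 0 or self.y_score.max() > 1):
            raise ValueError("y_score must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.y_true)

    def replace(self, **changes) -> "LabeledPredictions":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class _Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)

    @property
    def fnr(self) -> float:
        return 1.0 - self.tpr


@dataclass(frozen=True)
class GroupRates:
    """Per-group confusion counts/rates plus the designated pair's gaps."""

    privileged: object
    unprivileged: object
    by_group: Mapping[object, _Confusion]
    delta_tpr: float
    delta_fpr: float

    def confusion(self, group: object) -> _Confusion:
        return self.by_group[group]

    def tpr(self, group: object) -> float:
        return self.by_group[group].tpr

    def fpr(self, group: object) -> float:
        return self.by_group[group].fpr


def _confusion_for(y_true: np.ndarray, y_pred: np.ndarray, group: object) -> _Confusion:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    if tp + fn == 0:
        raise UndefinedRateError(
            f"TPR undefined for group {group!r}: no positive true labels"
        )
    if fp + tn == 0:
        raise UndefinedRateError(
            f"FPR undefined for group {group!r}: no negative true labels"
        )
    return _Confusion(tp=tp, fp=fp, tn=tn, fn=fn)


def _group_mask(lp: LabeledPredictions, g: object) -> np.ndarray:
    mask = lp.group == g
    if not mask.any():
        raise ValueError(f"group {g!r} not present in the data")
    return mask


def group_confusion(
    lp: LabeledPredictions, privileged: object, unprivileged: object
) -> GroupRates:
    """Confusion counts and TPR/FPR per group, plus |gap| for the pair."""
    by_group: dict[object, _Confusion] = {}
    for g in (privileged, unprivileged):
        mask = _group_mask(lp, g)
        by_group[g] = _confusion_for(lp.y_true[mask], lp.y_pred[mask], g)
    delta_tpr = abs(by_group[unprivileged].tpr - by_group[privileged].tpr)
    delta_fpr = abs(by_group[unprivileged].fpr - by_group[privileged].fpr)
    return GroupRates(
        privileged=privileged,
        unprivileged=unprivileged,
        by_group=by_group,
        delta_tpr=delta_tpr,
        delta_fpr=delta_fpr,
    )


def mean_outcome_difference(
    lp: LabeledPredictions,
    privileged: object,
    unprivileged: object,
    outcome: str = "true",
) -> float:
    """mean(outcome | unprivileged) - mean(outcome | privileged).

    ``outcome`` selects the column: ``"true"`` for the observed label,
    ``"pred"`` for the model's predicted label.
    """
    y = {"true": lp.y_true, "pred": lp.y_pred}[outcome]
    mu = float(np.mean(y[_group_mask(lp, unprivileged)]))
    mp = float(np.mean(y[_group_mask(lp, privileged)]))
    return mu - mp


def demographic_parity_difference(
    lp: LabeledPredictions, privileged: object, unprivileged: object
) -> float:
    """P(Yhat=1 | unprivileged) - P(Yhat=1 | privileged)."""
    pu = float(np.mean(lp.y_pred[_group_mask(lp, unprivileged)]))
    pp = float(np.mean(lp.y_pred[_group_mask(lp, privileged)]))
    return pu - pp


def disparate_impact(
    lp: LabeledPredictions, privileged: object, unprivileged: object
) -> float:
    """P(Yhat=1 | unprivileged) / P(Yhat=1 | privileged)."""
    pu = float(np.mean(lp.y_pred[_group_mask(lp, unprivileged)]))
    pp = float(np.mean(lp.y_pred[_group_mask(lp, privileged)]))
    if pp == 0:
        raise ZeroDivisionError(
            f"privileged group {privileged!r} has zero favourable-outcome rate; "
            "disparate impact is undefined"
        )
    return pu / pp


def equal_opportunity_difference(gr: GroupRates) -> float:
    """TPR(unprivileged) - TPR(privileged)."""
    return gr.tpr(gr.unprivileged) - gr.tpr(gr.privileged)


def average_odds_difference(gr: GroupRates) -> float:
    """Mean of the FPR gap and the TPR gap (unprivileged minus privileged)."""
    d_fpr = gr.fpr(gr.unprivileged) - gr.fpr(gr.privileged)
    d_tpr = gr.tpr(gr.unprivileged) - gr.tpr(gr.privileged)
    return 0.5 * (d_fpr + d_tpr)


def theil_index(lp: LabeledPredictions) -> float:
    """Generalised entropy index (alpha=1) of benefits b_i = yhat_i - y_i + 1.

    Zero iff every subject receives the same benefit; grows with the
    inequality of prediction errors across subjects.
    """
    if len(lp) < 1:
        raise ValueError("theil_index requires at least one subject")
    b = lp.y_pred.astype(float) - lp.y_true.astype(float) + 1.0
    mu = float(b.mean())
    if mu == 0:
        raise ValueError("all benefits are zero; Theil index undefined")
    ratio = b / mu
    pos = ratio > 0
    terms = np.zeros_like(ratio)
    terms[pos] = ratio[pos] * np.log(ratio[pos])
    return float(terms.mean())


def balanced_accuracy(lp: LabeledPredictions) -> float:
    """(TPR + TNR) / 2 over the pooled sample."""
    conf = _confusion_for(lp.y_true, lp.y_pred, "<pooled>")
    tnr = 1.0 - conf.fpr
    return 0.5 * (conf.tpr + tnr)


@dataclass(frozen=True)
class FairnessReport:
    """Flat bundle of the group-fairness statistics for one model run."""

    mean_outcome_difference: float
    disparate_impact: float
    demographic_parity_difference: float
    equal_opportunity_difference: float
    average_odds_difference: float
    theil_index: float
    accuracy: float
    balanced_accuracy: float
    delta_tpr: float
    delta_fpr: float
    privileged: object
    unprivileged: object

    _LABELS = {
        "mean_outcome_difference": "Difference in Mean Outcomes",
        "disparate_impact": "Disparate impact",
        "demographic_parity_difference": "Demographic parity difference",
        "equal_opportunity_difference": "Equal opportunity difference",
        "average_odds_difference": "Average odds difference",
        "theil_index": "Theil index",
        "accuracy": "Classification accuracy",
        "balanced_accuracy": "Balanced classification accuracy",
        "delta_tpr": "TPR gap",
        "delta_fpr": "FPR gap",
    }

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._LABELS}
        d["privileged"] = self.privileged
        d["unprivileged"] = self.unprivileged
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=str, **kw)

    def to_csv_row(self, run_id: str) -> dict:
        row = {"run_id": run_id}
        row.update({label: getattr(self, k) for k, label in self._LABELS.items()})
        return row


def compute_report(
    lp: LabeledPredictions,
    privileged: object,
    unprivileged: object,
    outcome_for_mean: str = "true",
) -> FairnessReport:
    """Compute the full fairness metric suite for one prediction set."""
    gr = group_confusion(lp, privileged, unprivileged)
    return FairnessReport(
        mean_outcome_difference=mean_outcome_difference(
            lp, privileged, unprivileged, outcome=outcome_for_mean
        ),
        disparate_impact=disparate_impact(lp, privileged, unprivileged),
        demographic_parity_difference=demographic_parity_difference(
            lp, privileged, unprivileged
        ),
        equal_opportunity_difference=equal_opportunity_difference(gr),
        average_odds_difference=average_odds_difference(gr),
        theil_index=theil_index(lp),
        accuracy=float(np.mean(lp.y_true == lp.y_pred)),
        balanced_accuracy=balanced_accuracy(lp),
        delta_tpr=gr.delta_tpr,
        delta_fpr=gr.delta_fpr,
        privileged=privileged,
        unprivileged=unprivileged,
    )
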