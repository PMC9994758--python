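"""Ordinal multi-label evaluation of phenology predictions.

Predictions and ground observations are compared on the 16-level
metaclass scale.  The suite covers:

* maxdiff-o accuracy — fraction of predictions displaced by at most
  ``o`` positions on the metaclass scale (o in 0..3; larger errors fall
  in a diff-3+ bin),
* Cohen's kappa and its linear / quadratic weighted variants over the
  metaclass indices,
* NDCG@2 over the ranked stages, with relevance 2 for the true primary
  stage and 1 for the true secondary,
* per-metaclass mean displacement (confusion row x |i-j| weights),
* the 6x6 principal-stage confusion matrix, and
* the early/middle/late chronological order of repeated observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .stages import Metaclass, N_METACLASSES, PhenologyStage, displacement

__all__ = [
    "maxdiff_accuracy",
    "kappa",
    "ndcg_at_2",
    "displacement_table",
    "principal_confusion",
    "order_of_observation",
    "EvaluationReport",
    "evaluate",
]

_LOG2_3 = float(np.log2(3.0))


def _indices(metaclasses: Sequence[Metaclass]) -> np.ndarray:
    return np.array([mc.index for mc in metaclasses], dtype=int)


def maxdiff_accuracy(
    predictions: Sequence[Metaclass], truths: Sequence[Metaclass], o: int
) -> float:
    """Fraction of predictions with metaclass displacement <= o."""
    if len(predictions) == 0:
        raise ValueError("no predictions to evaluate")
    if len(predictions) != len(truths):
        raise ValueError("prediction/truth lists are not aligned")
    disp = np.abs(_indices(predictions) - _indices(truths))
    return float(np.mean(disp <= o))


def kappa(
    predictions: Sequence[Metaclass],
    truths: Sequence[Metaclass],
    weighting: Optional[str] = None,
) -> float:
    """Cohen's kappa on metaclass indices; weighting None|'linear'|'quadratic'.

    Returns NaN (with a warning) for degenerate single-class marginals,
    where chance agreement is undefined.
    """
    if weighting not in (None, "none", "linear", "quadratic"):
        raise ValueError(f"unknown weighting {weighting!r}")
    y_pred = _indices(predictions)
    y_true = _indices(truths)
    if len(np.unique(np.concatenate([y_pred, y_true]))) < 2:
        warnings.warn("kappa undefined for single-class data; returning NaN")
        return float("nan")
    w = None if weighting in (None, "none") else weighting
    return float(
        cohen_kappa_score(y_true, y_pred, labels=np.arange(N_METACLASSES), weights=w)
    )


def ndcg_at_2(
    ranked_stages: Sequence[PhenologyStage], truth: Metaclass
) -> float:
    """NDCG over the top-2 ranked stages for one element.

    Relevance is 2 for the true primary stage, 1 for the true secondary,
    0 otherwise.  DCG discounts the second slot by log2(3); the ideal
    DCG places the primary first and, when a secondary exists, the
    secondary next.
    """
    top = list(ranked_stages[:2])
    if len(top) < 2 or top[0] == top[1]:
        raise ValueError("need two distinct ranked stages")

    def rel(stage: PhenologyStage) -> float:
        if stage == truth.primary:
            return 2.0
        if truth.secondary is not None and stage == truth.secondary:
            return 1.0
        return 0.0

    dcg = rel(top[0]) + rel(top[1]) / _LOG2_3
    idcg = 2.0 + (1.0 / _LOG2_3 if truth.secondary is not None else 0.0)
    return dcg / idcg


def displacement_table(
    predictions: Sequence[Metaclass],
    truths: Sequence[Metaclass],
    min_support: int = 10,
) -> pd.DataFrame:
    """Per-truth-metaclass mean displacement, for classes with enough support.

    Each reported row is the truth class's row-normalized confusion row
    multiplied by |i - j| weights and summed — i.e. the mean ordinal
    error in metaclass displacement units.  A final ``__average__`` row
    carries the support-weighted mean over the reported classes.
    """
    y_true = _indices(truths)
    y_pred = _indices(predictions)
    rows = []
    total_support = 0
    total_weighted = 0.0
    for idx in range(N_METACLASSES):
        mask = y_true == idx
        support = int(mask.sum())
        if support < min_support:
            continue
        mean_disp = float(np.abs(y_pred[mask] - y_true[mask]).mean())
        mc = _metaclass_from_index(idx)
        rows.append({"metaclass": str(mc), "support": support, "displacement": mean_disp})
        total_support += support
        total_weighted += mean_disp * support
    table = pd.DataFrame(rows, columns=["metaclass", "support", "displacement"])
    if total_support:
        table.loc[len(table)] = {
            "metaclass": "__average__",
            "support": total_support,
            "displacement": total_weighted / total_support,
        }
    return table


def _metaclass_from_index(idx: int) -> Metaclass:
    from .stages import enumerate_metaclasses

    return enumerate_metaclasses()[idx]


def principal_confusion(
    predictions: Sequence[Metaclass], truths: Sequence[Metaclass]
) -> Tuple[pd.DataFrame, float]:
    """6x6 primary-stage confusion matrix (rows truth) and overall accuracy."""
    y_true = [int(mc.primary) for mc in truths]
    y_pred = [int(mc.primary) for mc in predictions]
    labels = [int(s) for s in PhenologyStage]
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    codes = [s.code for s in PhenologyStage]
    frame = pd.DataFrame(cm, index=codes, columns=codes)
    accuracy = float(np.trace(cm) / cm.sum())
    return frame, accuracy


def order_of_observation(observations: pd.DataFrame) -> pd.Series:
    """Label each visit early/middle/late within its same-stage run.

    ``observations`` needs columns ``field_id``, ``doy`` (or
    ``visit_doy``) and ``primary`` (stage code).  Within each field,
    consecutive visits sharing a primary stage form a run; runs of 3-5
    visits mark the first as early and the last as late, runs of 6 or
    more mark the first two and last two, and 1-2 visit runs are labeled
    degenerately (single visit -> early).
    """
    doy_col = "doy" if "doy" in observations.columns else "visit_doy"
    out = pd.Series(index=observations.index, dtype=object)
    for _, grp in observations.groupby("field_id", sort=False):
        grp = grp.sort_values(doy_col)
        stages = grp["primary"].to_numpy()
        run_start = 0
        positions = grp.index.to_numpy()
        for i in range(1, len(stages) + 1):
            if i == len(stages) or stages[i] != stages[run_start]:
                run_idx = positions[run_start:i]
                out.loc[run_idx] = _label_run(len(run_idx))
                run_start = i
    return out


def _label_run(n: int) -> List[str]:
    if n == 1:
        return ["early"]
    if n == 2:
        return ["early", "late"]
    if n <= 5:
        return ["early"] + ["middle"] * (n - 2) + ["late"]
    return ["early", "early"] + ["middle"] * (n - 4) + ["late", "late"]


@dataclass
class EvaluationReport:
    """Bundle of every metric for one prediction/truth pairing."""

    n: int
    maxdiff: Dict[int, float]
    cohens_kappa: float
    weighted_kappa_linear: float
    weighted_kappa_quadratic: float
    ndcg_at_2: Optional[float]
    displacement: pd.DataFrame
    principal_confusion: pd.DataFrame
    principal_accuracy: float
    diff_counts: Dict[str, int] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": "1.0",
            "n": self.n,
            "maxdiff": {str(o): v for o, v in self.maxdiff.items()},
            "cohens_kappa": self.cohens_kappa,
            "weighted_kappa_linear": self.weighted_kappa_linear,
            "weighted_kappa_quadratic": self.weighted_kappa_quadratic,
            "ndcg_at_2": self.ndcg_at_2,
            "displacement": self.displacement.to_dict(orient="records"),
            "principal_confusion": self.principal_confusion.to_dict(),
            "principal_accuracy": self.principal_accuracy,
            "diff_counts": self.diff_counts,
        }


def evaluate(
    predictions: Sequence[Metaclass],
    truths: Sequence[Metaclass],
    rankings: Optional[Sequence[Sequence[PhenologyStage]]] = None,
    min_support: int = 10,
) -> EvaluationReport:
    """Full evaluation suite; ``rankings`` (ranked stages) enables NDCG@2."""
    disp = np.abs(_indices(predictions) - _indices(truths))
    maxdiff = {o: float(np.mean(disp <= o)) for o in (0, 1, 2, 3)}
    binned = np.minimum(disp, 3)
    diff_counts = {f"diff-{o}{'+' if o == 3 else ''}": int((binned == o).sum()) for o in range(4)}
    ndcg = None
    if rankings is not None:
        ndcg = float(
            np.mean([ndcg_at_2(r, t) for r, t in zip(rankings, truths)])
        )
    table = displacement_table(predictions, truths, min_support)
    cm, acc = principal_confusion(predictions, truths)
    return EvaluationReport(
        n=len(predictions),
        maxdiff=maxdiff,
        cohens_kappa=kappa(predictions, truths, None),
        weighted_kappa_linear=kappa(predictions, truths, "linear"),
        weighted_kappa_quadratic=kappa(predictions, truths, "quadratic"),
        ndcg_at_2=ndcg,
        displacement=table,
        principal_confusion=cm,
        principal_accuracy=acc,
        diff_counts=diff_counts,
    )
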