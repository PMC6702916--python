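"""Scoring a separation against truth labels.

The symbiont is the positive class: it is the target of the separation, and
precision/recall on symbiont calls is what an assembly downstream cares
about. Fragments flagged degenerate upstream (no scorable k-mers) are counted
in the confusion matrix like any other call but also reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .classify import FragmentScore
from .errors import InputMismatchError

__all__ = ["EvaluationReport", "evaluate_separation", "posterior_summary"]


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    n_degenerate: int = 0
    posterior_summary: Dict[str, Dict[str, float]] = field(default_factory=dict)

    @property
    def n_fragments(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "accuracy": self.accuracy,
            "n_degenerate": self.n_degenerate,
            "posterior_summary": self.posterior_summary,
        }


def evaluate_separation(
    predicted: Mapping[str, str],
    truth: Mapping[str, str],
    *,
    scores: Optional[Sequence[FragmentScore]] = None,
) -> EvaluationReport:
    """Confusion counts and rates of predicted vs truth origins.

    Both mappings take fragment id -> "host" | "symbiont" and must cover the
    same ids. When per-fragment scores are supplied, per-truth-class
    posterior summaries and the degenerate count are attached.
    """
    missing = sorted(set(truth) - set(predicted))
    extra = sorted(set(predicted) - set(truth))
    if missing or extra:
        detail = []
        if missing:
            detail.append(f"missing from predictions: {missing[:5]}")
        if extra:
            detail.append(f"absent from truth: {extra[:5]}")
        raise InputMismatchError(
            "predicted and truth ids differ — " + "; ".join(detail)
        )
    tp = fp = tn = fn = 0
    for fid, t in truth.items():
        p = predicted[fid]
        if t == "symbiont":
            tp += p == "symbiont"
            fn += p != "symbiont"
        else:
            tn += p != "symbiont"
            fp += p == "symbiont"
    n = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    report = EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall, f1=f1,
        accuracy=(tp + tn) / n if n else 0.0,
    )
    if scores is not None:
        report.n_degenerate = sum(s.degenerate for s in scores)
        report.posterior_summary = posterior_summary(scores, truth)
    return report


def posterior_summary(
    scores: Sequence[FragmentScore], truth: Mapping[str, str]
) -> Dict[str, Dict[str, float]]:
    """Mean/median posterior of symbiont origin per truth class."""
    out: Dict[str, Dict[str, float]] = {}
    for cls in ("host", "symbiont"):
        vals = np.array(
            [s.posterior_q for s in scores if truth.get(s.id) == cls]
        )
        if vals.size:
            out[cls] = {
                "mean_posterior_q": float(vals.mean()),
                "median_posterior_q": float(np.median(vals)),
                "n": int(vals.size),
            }
    return out
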