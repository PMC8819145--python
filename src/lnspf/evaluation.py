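"""Evaluate a ranking against an essential-protein label set.

Three standard views:

* top-K% counts — how many labeled essentials land in the highest-scoring
  ceil(N·K/100) proteins;
* the jackknife curve — cumulative essentials among the top n as n grows;
* ROC / AUC — threshold sweep over the final scores, with unlabeled
  proteins treated as negatives and the AUC equal to the Mann–Whitney
  concordance probability (ties counted 1/2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .pipeline import RankedList, top_k_percent


@dataclass
class EvaluationReport:
    topk_counts: dict
    jackknife: np.ndarray
    roc_points: np.ndarray  # (FPR, TPR) rows
    auc: float

    def to_dict(self) -> dict:
        return {
            "topk_counts": {str(k): int(v) for k, v in
                            self.topk_counts.items()},
            "jackknife": [int(c) for c in self.jackknife],
            "auc": float(self.auc),
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def topk_report(ranked: RankedList, labels, ks) -> dict:
    """Count labeled essentials inside each top-K% slice."""
    labels = set(labels)
    if not labels:
        raise ValueError("empty essential-protein label set")
    return {k: sum(p in labels for p in top_k_percent(ranked, k))
            for k in ks}


def jackknife_curve(ranked: RankedList, labels, cutoff: int) -> np.ndarray:
    """Cumulative label count among the top n ranked proteins, n=1..cutoff."""
    if cutoff > len(ranked):
        raise ValueError(f"cutoff {cutoff} exceeds ranking length "
                         f"{len(ranked)}")
    labels = set(labels)
    hits = np.fromiter((p in labels for p in ranked.proteins()[:cutoff]),
                       dtype=int, count=cutoff)
    return np.cumsum(hits)


def roc_auc(scores, proteins, labels):
    """ROC points and AUC of per-protein scores against a label set.

    ``scores`` aligns with ``proteins``; proteins absent from ``labels``
    count as negatives.  Needs at least one protein of each class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = set(labels)
    y = np.fromiter((p in labels for p in proteins), dtype=int,
                    count=len(scores))
    if y.all() or not y.any():
        raise ValueError("ROC needs both a positive and a negative protein")
    fpr, tpr, _ = roc_curve(y, scores)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(y, scores))


def evaluate(ranked: RankedList, labels, ks=(1, 5, 10, 15, 20, 25),
             cutoff: int | None = None) -> EvaluationReport:
    """Full report for a ranking whose entries carry the final scores."""
    cutoff = cutoff if cutoff is not None else len(ranked)
    proteins = ranked.proteins()
    scores = [s for _, s in ranked.entries]
    points, auc = roc_auc(scores, proteins, labels)
    return EvaluationReport(
        topk_counts=topk_report(ranked, labels, ks),
        jackknife=jackknife_curve(ranked, labels, cutoff),
        roc_points=points,
        auc=auc,
    )
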