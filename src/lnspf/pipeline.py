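"""End-to-end orchestration: run the ranking and slice top-K% candidates.

Thin functional wrappers over :class:`lnspf.estimator.LNSPF`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .estimator import LNSPF
from .io import ExpressionMatrix, PPINetwork, RunConfig


@dataclass
class RankedList:
    """Proteins ordered by descending final score.

    ``entries`` holds (protein, T^Final) pairs; ``extras`` carries the
    intermediate stage scores (CScore, Y^Final) and iteration counts for
    reporting and manifests.
    """

    entries: list
    tie_break: str = "input protein order"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranked scores must be non-increasing")

    def __len__(self):
        return len(self.entries)

    def proteins(self) -> list:
        return [p for p, _ in self.entries]


def run_lnspf(net: PPINetwork, expr: ExpressionMatrix, sub: dict,
              os_map: dict, cfg: RunConfig | None = None) -> RankedList:
    """Execute the full pipeline and rank all proteins of the network."""
    cfg = cfg or RunConfig()
    model = LNSPF.from_config(cfg).fit(net, expr, sub, os_map)
    score = model.score_dict()
    return RankedList(
        entries=list(model.ranking_),
        tie_break=model.tie_break_,
        extras={
            "cscore": {p: float(v) for p, v in zip(model.proteins_,
                                                   model.cscore_)},
            "y_final": {p: float(v) for p, v in zip(model.proteins_,
                                                    model.y_final_)},
            "t_final": score,
            "iterations": {"y": model.n_iter_y_, "t": model.n_iter_t_},
            "feature_weights": model.feature_weights_.tolist(),
        },
    )


def top_k_percent(ranked: RankedList, k_percent: float) -> list:
    """First ceil(N * k / 100) proteins of the ranking."""
    if not 0 < k_percent <= 100:
        raise ValueError(f"k_percent must be in (0, 100], got {k_percent}")
    n = len(ranked)
    cut = math.ceil(n * k_percent / 100.0)
    return ranked.proteins()[:cut]
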