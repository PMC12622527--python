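"""Pose-level aggregation and two-model weighted consensus.

Each compound usually carries several docked poses.  A single per-model
compound score is produced by one of three strategies — ``max`` (best
rescored pose regardless of docking rank, the recommended default),
``top1`` (the docking engine's top pose) or ``average`` — and the two
models' aggregated scores are then mixed by a fixed, non-trainable
consensus weight: balanced 50/50, or the recommended imbalanced 70/30
(PS-role scorer 70%, PB-role 30%).  Aggregation happens per model before
consensus: each model independently picks its own best pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Strategy",
    "CompoundScore",
    "ConsensusScorer",
    "BALANCED_WEIGHTS",
    "IMBALANCED_WEIGHTS",
    "aggregate_poses",
    "consensus_score",
    "score_library",
]

Strategy = Literal["max", "top1", "average"]

#: Balanced consensus: plain average of the two scorers.
BALANCED_WEIGHTS = (0.5, 0.5)
#: Imbalanced consensus: PB-role 30%, PS-role 70% (recommended).
IMBALANCED_WEIGHTS = (0.3, 0.7)


def aggregate_poses(scores: Sequence[float], ranks: Sequence[int] | None = None,
                    strategy: Strategy = "max") -> float:
    """Collapse per-pose scores of one compound into a single score."""
    if len(scores) == 0:
        raise ValueError("no pose scores to aggregate")
    s = np.asarray(scores, dtype=float)
    if strategy == "max":
        return float(s.max())
    if strategy == "average":
        return float(s.mean())
    if strategy == "top1":
        if ranks is None:
            ranks = range(1, len(s) + 1)
        ranks = list(ranks)
        return float(s[ranks.index(min(ranks))])
    raise ValueError(f"unknown strategy {strategy!r}")


def consensus_score(score_a: float, score_b: float,
                    weights: tuple[float, float] = IMBALANCED_WEIGHTS) -> float:
    """Fixed-weight convex combination w_a·a + w_b·b of two model scores."""
    w_a, w_b = weights
    if w_a < 0 or w_b < 0 or abs(w_a + w_b - 1.0) > 1e-9:
        raise ValueError(f"weights must be non-negative and sum to 1, got {weights}")
    return w_a * score_a + w_b * score_b


@dataclass
class CompoundScore:
    """Per-compound scoring record."""

    compound_id: str
    pose_scores: list[float]
    pose_ranks: list[int]
    aggregated: float
    strategy: Strategy

    def __post_init__(self) -> None:
        if not 0.0 <= self.aggregated <= 1.0:
            raise ValueError("aggregated score must lie in [0, 1]")


@dataclass
class ConsensusScorer:
    """Two trained scorers plus their fixed mixing weights.

    ``scorer_a`` plays the PB role (weight ``weights[0]``), ``scorer_b``
    the PS role (weight ``weights[1]``).
    """

    scorer_a: object
    scorer_b: object
    weights: tuple[float, float] = IMBALANCED_WEIGHTS

    def __post_init__(self) -> None:
        w_a, w_b = self.weights
        if w_a < 0 or w_b < 0 or abs(w_a + w_b - 1.0) > 1e-9:
            raise ValueError("consensus weights must be non-negative and sum to 1")


def score_library(per_pose_scores: pd.DataFrame,
                  weights: tuple[float, float] = IMBALANCED_WEIGHTS,
                  strategy: Strategy = "max") -> pd.DataFrame:
    """Aggregate and mix per-pose scores of a whole library.

    ``per_pose_scores`` columns: ``compound_id``, ``pose_rank``,
    ``score_a``, ``score_b`` (one row per pose).  Per compound, each
    model's pose scores are aggregated with the strategy, then combined by
    the consensus weights.  Output is ranked descending by consensus score
    with deterministic compound_id tie-breaking, so downstream enrichment
    numbers are reproducible.
    """
    required = {"compound_id", "pose_rank", "score_a", "score_b"}
    missing = required - set(per_pose_scores.columns)
    if missing:
        raise ValueError(f"per-pose table missing columns: {sorted(missing)}")
    rows = []
    for cid, grp in per_pose_scores.groupby("compound_id", sort=True):
        ranks = grp["pose_rank"].tolist()
        agg_a = aggregate_poses(grp["score_a"].tolist(), ranks, strategy)
        agg_b = aggregate_poses(grp["score_b"].tolist(), ranks, strategy)
        rows.append({
            "compound_id": cid,
            "score_a": agg_a,
            "score_b": agg_b,
            "consensus": consensus_score(agg_a, agg_b, weights),
            "n_poses": len(grp),
        })
    out = pd.DataFrame(rows)
    out = out.sort_values(["consensus", "compound_id"],
                          ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
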