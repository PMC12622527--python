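"""Virtual-screening and docking evaluation metrics.

Screening power is measured by early-recognition metrics on a ranked
library with binary active/decoy labels:

* **EF x%** — enrichment factor: the concentration of actives in the top
  x% of the ranking relative to the library-wide active rate.  The top set
  holds ⌈x·N⌉ compounds (ceiling, so tiny fractions of small libraries are
  never empty).  A random ranking has expected EF 1.
* **BEDROC(α)** — Truchon–Bayly Boltzmann-enhanced discrimination of ROC,
  an exponentially early-weighted rank sum normalised to [0, 1]; α = 80.5
  concentrates ~80% of the weight in the top ~2% of the list.
* **AUROC** — probability a random active outranks a random decoy
  (Mann–Whitney; ties count ½).
* **Spearman R_s** between predicted scores and experimental affinities.
* **Docking success rate** — fraction of top-ranked poses within an RMSD
  threshold of the crystal pose.

Ties in scores are resolved upstream by deterministic compound-id ordering
(see :mod:`ibvs.scoring`), keeping tie-sensitive EF values reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ScreenResult",
    "UndefinedMetricError",
    "enrichment_factor",
    "bedroc",
    "auroc",
    "spearman_rank",
    "docking_success_rate",
    "screening_report",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. single-class labels)."""


@dataclass
class ScreenResult:
    """Scored, labelled screening library (higher score = more active-like)."""

    compound_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    affinities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.compound_ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores and labels must have equal length")
        if self.affinities is not None:
            self.affinities = np.asarray(self.affinities, dtype=float)
            if len(self.affinities) != len(self.scores):
                raise ValueError("affinities length mismatch")

    def _require_both_classes(self) -> None:
        if self.labels.sum() == 0:
            raise UndefinedMetricError("no actives in the library")
        if self.labels.sum() == len(self.labels):
            raise UndefinedMetricError("no inactives in the library")

    def ranked_labels(self) -> np.ndarray:
        """Labels sorted by descending score, compound_id breaking ties."""
        order = np.lexsort((np.asarray(self.compound_ids), -self.scores))
        return self.labels[order]


def enrichment_factor(result: ScreenResult, fraction: float) -> float:
    """EF at a screening fraction; top-set size is ⌈fraction·N⌉."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    result._require_both_classes()
    ranked = result.ranked_labels()
    n = len(ranked)
    top = int(np.ceil(fraction * n))
    hits = int(ranked[:top].sum())
    total_actives = int(result.labels.sum())
    return (hits / top) / (total_actives / n)


def bedroc(result: ScreenResult, alpha: float = 80.5) -> float:
    """Truchon–Bayly BEDROC in [0, 1].

    BEDROC = RIE·(Ra·sinh(α/2)) / (cosh(α/2) − cosh(α/2 − α·Ra))
             + 1 / (1 − e^{α(1−Ra)})
    with RIE the normalised exponential sum over active relative ranks
    x_i = r_i/N and Ra the active fraction.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    result._require_both_classes()
    ranked = result.ranked_labels()
    n = len(ranked)
    n_act = int(ranked.sum())
    r_a = n_act / n
    ranks = np.nonzero(ranked == 1)[0] + 1  # 1-based positions of actives
    s = np.sum(np.exp(-alpha * ranks / n))
    rand_sum = n_act / n * (1.0 - np.exp(-alpha)) / (np.exp(alpha / n) - 1.0)
    rie = s / rand_sum
    sinh_a = np.sinh(alpha / 2.0)
    denom = np.cosh(alpha / 2.0) - np.cosh(alpha / 2.0 - alpha * r_a)
    return float(rie * r_a * sinh_a / denom + 1.0 / (1.0 - np.exp(alpha * (1.0 - r_a))))


def auroc(result: ScreenResult) -> float:
    """Mann–Whitney AUROC: P(random active outranks random inactive)."""
    result._require_both_classes()
    return float(roc_auc_score(result.labels, result.scores))


def spearman_rank(scores: Sequence[float], affinities: Sequence[float]) -> float:
    """Spearman rank correlation between predictions and affinities."""
    s = np.asarray(scores, dtype=float)
    a = np.asarray(affinities, dtype=float)
    if len(s) < 3:
        raise ValueError("Spearman needs at least 3 observations")
    if np.ptp(s) == 0 or np.ptp(a) == 0:
        raise UndefinedMetricError("Spearman undefined for a constant vector")
    return float(_stats.spearmanr(s, a).statistic)


def docking_success_rate(rmsds_of_top_pose: Sequence[float],
                         thresholds: Sequence[float] = (2.0, 2.5, 3.0)
                         ) -> dict[float, float]:
    """Fraction of top poses with RMSD ≤ each threshold (Å)."""
    r = np.asarray(rmsds_of_top_pose, dtype=float)
    if len(r) == 0:
        raise UndefinedMetricError("success rate undefined for an empty list")
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    return {float(t): float(np.mean(r <= t)) for t in thresholds}


def screening_report(result: ScreenResult,
                     ef_fractions: Sequence[float] = (0.005, 0.01, 0.05),
                     bedroc_alpha: float = 80.5) -> dict:
    """One-call summary: EF at each fraction, BEDROC and AUROC."""
    rep = {f"EF{100 * f:g}%": enrichment_factor(result, f) for f in ef_fractions}
    rep[f"BEDROC(alpha={bedroc_alpha:g})"] = bedroc(result, bedroc_alpha)
    rep["AUROC"] = auroc(result)
    return rep
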