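"""Additive feature attribution for trained scorers.

Tree-ensemble scorers admit exact additive attribution (TreeSHAP): for
every example, a base value plus one signed contribution per feature sums
to the model's margin (log-odds) output.  Attribution is computed on the
margin scale, where the additivity identity is exact; a probability-scale
display is a labelled sigmoid transform, not an additive decomposition.

Global importance ranks features by mean absolute contribution over a
dataset (the beeswarm ordering); local attribution orders one example's
contributions into a waterfall from base value to prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .training import TrainedScorer

__all__ = ["AttributionReport", "WaterfallRecord",
           "global_importance", "local_attribution"]


@dataclass
class AttributionReport:
    """Global attribution summary over a dataset."""

    base_value: float
    feature_names: tuple[str, ...]
    contributions: np.ndarray        # (n_examples, n_features), margin scale
    feature_values: np.ndarray       # matching raw feature values

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.contributions).mean(axis=0)

    def ranking(self) -> pd.DataFrame:
        """Features ranked by mean |contribution|, with signed summaries."""
        df = pd.DataFrame({
            "feature": self.feature_names,
            "mean_abs_contribution": self.mean_abs,
            "mean_contribution": self.contributions.mean(axis=0),
            # sign of the value-contribution association ("more-to-better"
            # shows as a positive correlation)
            "value_contribution_corr": [
                _safe_corr(self.feature_values[:, j], self.contributions[:, j])
                for j in range(len(self.feature_names))
            ],
        })
        df = df.sort_values(["mean_abs_contribution", "feature"],
                            ascending=[False, True], kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        return df.reset_index(drop=True)

    def beeswarm_export(self) -> pd.DataFrame:
        """Long-form (feature, value, contribution) table for beeswarm plots."""
        n, p = self.contributions.shape
        return pd.DataFrame({
            "feature": np.repeat(self.feature_names, n),
            "value": self.feature_values.T.ravel(),
            "contribution": self.contributions.T.ravel(),
        })


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _contributions(model: TrainedScorer, features) -> tuple[np.ndarray, float, np.ndarray]:
    contrib = model.predict_contributions(features)
    base = float(contrib[0, -1])
    if isinstance(features, pd.DataFrame):
        values = features[list(model.feature_names)].to_numpy(dtype=float)
    else:
        values = np.asarray(features, dtype=float)
        if values.ndim == 1:
            values = values[None, :]
    return contrib[:, :-1], base, values


def global_importance(model: TrainedScorer, features) -> AttributionReport:
    """Attribution over a dataset, ranked by mean absolute contribution."""
    if len(features) == 0:
        raise ValueError("need at least one example")
    contrib, base, values = _contributions(model, features)
    return AttributionReport(base, model.feature_names, contrib, values)


@dataclass
class WaterfallRecord:
    """One example's ordered walk from base value to margin prediction."""

    base_value: float
    prediction_margin: float
    prediction_probability: float
    steps: pd.DataFrame  # feature, value, contribution; descending |contribution|

    def cumulative(self) -> np.ndarray:
        """Running totals base → prediction; last entry equals the margin."""
        return self.base_value + np.cumsum(self.steps["contribution"].to_numpy())


def local_attribution(model: TrainedScorer, example) -> WaterfallRecord:
    """Per-feature additive contributions for a single example.

    Positive contributions push the score up.  ``base + Σ contributions``
    equals the margin prediction to numerical precision.
    """
    from .schema import FeatureVector
    if isinstance(example, FeatureVector):
        values = example.as_array()[None, :]
    else:
        values = np.asarray(example, dtype=float)
        if values.ndim == 1:
            values = values[None, :]
    contrib, base, vals = _contributions(model, values)
    margin = base + float(contrib[0].sum())
    steps = pd.DataFrame({
        "feature": model.feature_names,
        "value": vals[0],
        "contribution": contrib[0],
    })
    steps = steps.iloc[np.argsort(-np.abs(steps["contribution"].to_numpy()),
                                  kind="stable")].reset_index(drop=True)
    return WaterfallRecord(base, margin, float(1.0 / (1.0 + np.exp(-margin))), steps)
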