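"""End-to-end conveniences tying the modules into one screen workflow."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curation import TrainingSet, apply_maxabs, fit_maxabs
from .evaluation import ScreenResult
from .scoring import consensus_score
from .training import TrainedScorer, TrainingConfig, train_scorer

__all__ = ["training_set_from_frame", "fit_screen_scorer", "score_screen",
           "consensus_screen"]

_META_COLS = ("compound_id", "pose_id", "pose_rank", "label", "provenance",
              "target_id", "weight")


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in _META_COLS]


def training_set_from_frame(df: pd.DataFrame, schema_id: str = "synthetic",
                            scale: bool = True) -> tuple[TrainingSet, object]:
    """Build a (scaled) TrainingSet from a labelled feature table."""
    cols = feature_columns(df)
    feats = df[cols]
    scaler = fit_maxabs(feats, schema_id) if scale else None
    X = apply_maxabs(feats, scaler) if scale else feats
    weights = (df["weight"].to_numpy(dtype=float)
               if "weight" in df.columns else np.ones(len(df)))
    ts = TrainingSet(X.to_numpy(dtype=float), df["label"].to_numpy(dtype=int),
                     weights, schema_id, tuple(cols))
    return ts, scaler


def fit_screen_scorer(train_df: pd.DataFrame,
                      config: TrainingConfig | None = None,
                      schema_id: str = "synthetic") -> TrainedScorer:
    """Fit scaler + scorer on one labelled screening table."""
    ts, scaler = training_set_from_frame(train_df, schema_id)
    return train_scorer(ts, config, scaler=scaler)


def score_screen(model: TrainedScorer, df: pd.DataFrame) -> ScreenResult:
    """Score a labelled screening table with one model."""
    feats = df[list(model.feature_names)]
    if model.scaler is not None:
        feats = apply_maxabs(feats, model.scaler)
    scores = model.predict_proba(feats)
    return ScreenResult(df["compound_id"].tolist(), scores,
                        df["label"].to_numpy(dtype=int))


def consensus_screen(model_a: TrainedScorer, model_b: TrainedScorer,
                     df: pd.DataFrame,
                     weights: tuple[float, float] = (0.5, 0.5)) -> ScreenResult:
    """Score a table with two models and mix by fixed consensus weights."""
    ra = score_screen(model_a, df)
    rb = score_screen(model_b, df)
    mixed = np.array([consensus_score(a, b, weights)
                      for a, b in zip(ra.scores, rb.scores)])
    return ScreenResult(ra.compound_ids, mixed, ra.labels)
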