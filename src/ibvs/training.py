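"""Imbalance-weighted gradient-boosted scorers.

The scorer is a binary XGBoost classifier trained directly on the
imbalanced active/decoy table — no resampling or augmentation.  Class
imbalance is compensated in the loss by weighting every positive example by

    scale_pos_weight = (len(y) - sum(y)) / sum(y),

which equalises the total weight of the two classes, and the optimisation
target is validation AUCPR, the metric that actually tracks minority-class
(active) retrieval.  Hyperparameters come from a seeded random search:
each trial trains up to ``max_rounds_search`` rounds with early stopping,
and the best trial's parameters are refit with a much larger round budget.

The reference-scale schedule mirrors production practice (100 trials ×
2000 rounds, early stop 50; final refit up to 50 000 rounds, early stop
100); :meth:`TrainingConfig.desk` is the small profile used throughout the
test suite and examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import train_test_split

from .curation import ScalerState, TrainingSet, compute_scale_pos_weight

__all__ = [
    "TrainingConfig",
    "TrainedScorer",
    "weighted_log_loss",
    "train_scorer",
    "predict_proba",
]

EPS = 1e-15


def weighted_log_loss(y, p, w=None) -> float:
    """Weighted binary cross-entropy −(1/N) Σ wᵢ[yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)].

    Probabilities are clipped to [ε, 1−ε] with ε = 1e-15; with unit weights
    this is exactly the ordinary binary cross-entropy.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    if w.shape != y.shape:
        raise ValueError(f"shape mismatch: w {w.shape} vs y {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


@dataclass
class TrainingConfig:
    """Search/refit schedule and hyperparameter ranges.

    ``param_space`` maps XGBoost parameter names to (low, high) ranges;
    ``log``-suffixed entries are sampled log-uniformly, integer ranges
    uniformly on integers.
    """

    search_trials: int = 100
    max_rounds_search: int = 2000
    early_stop_search: int = 50
    max_rounds_final: int = 50_000
    early_stop_final: int = 100
    objective_metric: str = "aucpr"
    val_fraction: float = 0.1
    seed: int = 42
    param_space: dict = field(default_factory=lambda: {
        "max_depth": ("int", 3, 10),
        "learning_rate": ("log", 0.01, 0.3),
        "subsample": ("uniform", 0.6, 1.0),
        "colsample_bytree": ("uniform", 0.5, 1.0),
        "min_child_weight": ("int", 1, 10),
        "gamma": ("uniform", 0.0, 5.0),
        "reg_lambda": ("log", 0.01, 10.0),
        "reg_alpha": ("uniform", 0.0, 5.0),
    })

    def __post_init__(self) -> None:
        for name in ("search_trials", "max_rounds_search", "early_stop_search",
                     "max_rounds_final", "early_stop_final"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk(cls, seed: int = 42, **overrides) -> "TrainingConfig":
        """Small-footprint profile for interactive and test-suite use."""
        kw = dict(search_trials=20, max_rounds_search=500, early_stop_search=30,
                  max_rounds_final=1000, early_stop_final=50, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    def sample_params(self, rng: np.random.Generator) -> dict:
        params = {}
        for name, (kind, lo, hi) in self.param_space.items():
            if kind == "int":
                params[name] = int(rng.integers(lo, hi + 1))
            elif kind == "log":
                params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                params[name] = float(rng.uniform(lo, hi))
        return params


@dataclass
class TrainedScorer:
    """Fitted booster plus the scaler and schema it expects its inputs in."""

    booster: xgb.Booster
    scaler: ScalerState | None
    schema_id: str
    feature_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def _matrix(self, features) -> xgb.DMatrix:
        if isinstance(features, pd.DataFrame):
            missing = set(self.feature_names) - set(features.columns)
            if missing:
                raise ValueError(
                    f"features missing schema columns: {sorted(missing)[:5]}")
            X = features[list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        return xgb.DMatrix(X, feature_names=list(self.feature_names), nthread=1)

    def predict_proba(self, features) -> np.ndarray:
        """Binding-confidence scores in [0, 1], one per row, order preserved."""
        return self.booster.predict(self._matrix(features), validate_features=False)

    def predict_contributions(self, features) -> np.ndarray:
        """Per-feature additive contributions on the margin (log-odds) scale.

        Returns an (n, p+1) array; the last column is the base value.  Rowwise,
        base + Σ contributions equals the margin prediction exactly (TreeSHAP).
        """
        return self.booster.predict(self._matrix(features), pred_contribs=True,
                                    validate_features=False)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(d / "booster.json"))
        if self.scaler is not None:
            self.scaler.to_json(d / "scaler.json")
        (d / "meta.json").write_text(json.dumps({
            "schema_id": self.schema_id,
            "feature_names": list(self.feature_names),
            "metadata": self.metadata,
        }, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedScorer":
        d = Path(directory)
        booster = xgb.Booster()
        booster.load_model(str(d / "booster.json"))
        meta = json.loads((d / "meta.json").read_text())
        scaler = None
        if (d / "scaler.json").exists():
            scaler = ScalerState.from_json(d / "scaler.json")
        return cls(booster, scaler, meta["schema_id"],
                   tuple(meta["feature_names"]), meta.get("metadata", {}))


def _base_params(spw: float, seed: int) -> dict:
    return {
        "objective": "binary:logistic",
        "eval_metric": "aucpr",
        "scale_pos_weight": spw,
        "tree_method": "hist",
        "nthread": 1,
        "seed": seed,
    }


def train_scorer(data: TrainingSet, config: TrainingConfig | None = None,
                 scaler: ScalerState | None = None,
                 validation: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> TrainedScorer:
    """Random-search then refit an XGBoost scorer maximising validation AUCPR.

    The positive-class weight is set from the training labels (Eq. of the
    class-balance identity: spw × n_pos = n_neg).  When no external
    validation pair is supplied, a seeded stratified ``val_fraction`` split
    is held out for early stopping and trial selection.  Deterministic for
    a fixed config, data and seed.
    """
    config = config or TrainingConfig.desk()
    if len(np.unique(data.y)) < 2:
        raise ValueError("training requires both classes")
    if validation is None:
        X_tr, X_val, y_tr, y_val = train_test_split(
            data.X, data.y, test_size=config.val_fraction,
            random_state=config.seed, stratify=data.y)
    else:
        X_tr, y_tr = data.X, data.y
        X_val, y_val = validation

    spw = compute_scale_pos_weight(y_tr)
    feature_names = list(data.feature_names) or [f"f{i}" for i in range(data.X.shape[1])]
    dtrain = xgb.DMatrix(X_tr, label=y_tr, feature_names=feature_names, nthread=1)
    dval = xgb.DMatrix(X_val, label=y_val, feature_names=feature_names, nthread=1)

    rng = np.random.default_rng(config.seed)
    best = {"score": -np.inf, "params": None, "trial": -1}
    trials_log = []
    for trial in range(config.search_trials):
        params = {**_base_params(spw, config.seed), **config.sample_params(rng)}
        evals_result: dict = {}
        bst = xgb.train(params, dtrain,
                        num_boost_round=config.max_rounds_search,
                        evals=[(dval, "val")],
                        early_stopping_rounds=config.early_stop_search,
                        evals_result=evals_result, verbose_eval=False)
        score = float(np.max(evals_result["val"]["aucpr"]))
        trials_log.append({"trial": trial, "aucpr": score,
                           "params": {k: v for k, v in params.items()
                                      if k in config.param_space}})
        if score > best["score"]:
            best = {"score": score, "params": params, "trial": trial}

    evals_result = {}
    final = xgb.train(best["params"], dtrain,
                      num_boost_round=config.max_rounds_final,
                      evals=[(dval, "val")],
                      early_stopping_rounds=config.early_stop_final,
                      evals_result=evals_result, verbose_eval=False)
    metadata = {
        "best_trial": best["trial"],
        "best_search_aucpr": best["score"],
        "final_val_aucpr": float(np.max(evals_result["val"]["aucpr"])),
        "rounds_used": int(final.best_iteration) + 1,
        "scale_pos_weight": spw,
        "seed": config.seed,
        "trials": trials_log,
    }
    return TrainedScorer(final, scaler, data.schema_id,
                         tuple(feature_names), metadata)


def predict_proba(model: TrainedScorer, features) -> np.ndarray:
    """Functional alias for :meth:`TrainedScorer.predict_proba`."""
    return model.predict_proba(features)
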