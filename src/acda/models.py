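"""The synergy predictors: ACDA, CDA, EN, EN-ACDA and their consensus.

* **ACDA** -- random forest regression on the four monotherapy-derived
  features (sens_a, sens_b, target indicator, cophenetic distance), with
  hyperparameters chosen by random search over a k-fold cross-validation
  score.
* **CDA** -- the predecessor baseline: logistic regression on the same
  features when the target is binary (synergy / no synergy), ordinary linear
  regression for continuous scores.  Logistic predictions are returned on
  the probability scale.
* **EN** -- random forest on one-hot encoded drug and model names only.
  Names outside the training vocabulary encode to all-zero blocks, which is
  what makes EN collapse when trained and tested on different studies.
* **EN-ACDA** -- the EN one-hot design concatenated with the four ACDA
  features, tuned like ACDA.
* **ACDA-EN-ACDA** -- the elementwise mean of ACDA and EN-ACDA predictions
  (see :func:`consensus_average`).

All fits are deterministic under a fixed seed: a single master seed derives
the tuning-sampler, fold-shuffling and forest seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, ParameterSampler

from .features import FEATURE_COLUMNS, KEY_COLUMNS

__all__ = [
    "SchemaError",
    "ModeError",
    "AlignmentError",
    "TuningConfig",
    "FittedModel",
    "DEFAULT_RF_PARAMS",
    "fit_acda",
    "fit_cda",
    "fit_en",
    "fit_en_acda",
    "predict",
    "consensus_average",
    "save_model",
    "load_model",
]


class SchemaError(ValueError):
    """Prediction input does not match the schema recorded at fit time."""


class ModeError(ValueError):
    """The requested CDA mode is incompatible with the targets."""


class AlignmentError(ValueError):
    """Two prediction vectors are not aligned on the same records."""


#: the untuned forest configuration; also the first candidate of every
#: random search, so the selected configuration can never score below it
DEFAULT_RF_PARAMS = {
    "n_estimators": 100,
    "max_depth": None,
    "min_samples_leaf": 1,
    "max_features": 1.0,
}

DEFAULT_SEARCH_SPACE = {
    "n_estimators": [100, 200, 500],
    "max_depth": [None, 5, 10, 20],
    "min_samples_leaf": [1, 2, 5, 10],
    "max_features": [1.0, "sqrt"],
}

FAST_SEARCH_SPACE = {
    "n_estimators": [100, 200],
    "max_depth": [None, 10],
    "min_samples_leaf": [1, 2, 5],
    "max_features": [1.0, "sqrt"],
}


@dataclass(frozen=True)
class TuningConfig:
    """Random-search specification for forest hyperparameters.

    ``n_iter`` configurations are sampled from ``search_space`` and scored by
    mean R^2 over ``k`` shuffled folds; the default (untuned) configuration
    is always evaluated alongside them.
    """

    search_space: dict = field(default_factory=lambda: dict(DEFAULT_SEARCH_SPACE))
    n_iter: int = 20
    k: int = 5

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    @classmethod
    def fast(cls) -> "TuningConfig":
        """Reduced search used by default inside repeated benchmarks."""
        return cls(search_space=dict(FAST_SEARCH_SPACE), n_iter=5, k=3)


@dataclass
class FittedModel:
    """A trained predictor plus the schema needed to apply it safely.

    ``kind`` selects the design construction at prediction time;
    one-hot vocabularies (EN / EN-ACDA) are frozen at fit.
    """

    method_tag: str
    kind: str  # "rf_features" | "linear" | "logistic" | "rf_onehot" | "rf_concat"
    estimator: object
    feature_columns: tuple[str, ...]
    drug_vocab: tuple[str, ...] = ()
    model_vocab: tuple[str, ...] = ()
    hyperparams: dict = field(default_factory=dict)
    seed: int | None = None
    cv_score_best: float | None = None
    cv_score_default: float | None = None

    @property
    def design_width(self) -> int:
        return len(self.feature_columns) + len(self.drug_vocab) + len(self.model_vocab)


def _derive_seeds(seed: int) -> tuple[int, int, int]:
    state = np.random.SeedSequence(seed).generate_state(3)
    return tuple(int(s % (2**31)) for s in state)  # type: ignore[return-value]


def _feature_block(table: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s): {missing}")
    return table.loc[:, list(columns)].to_numpy(dtype=float)


def _onehot_block(
    table: pd.DataFrame, drug_vocab: Sequence[str], model_vocab: Sequence[str]
) -> np.ndarray:
    """Indicator encoding of pair membership and model identity.

    Each drug column is 1 when the drug is either member of the pair (so the
    encoding is orientation-invariant); unseen names silently encode to
    zeros.
    """
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing key column(s): {missing}")
    n = len(table)
    block = np.zeros((n, len(drug_vocab) + len(model_vocab)))
    drug_pos = {d: i for i, d in enumerate(drug_vocab)}
    model_pos = {m: len(drug_vocab) + i for i, m in enumerate(model_vocab)}
    a = table["drug_a"].to_numpy()
    b = table["drug_b"].to_numpy()
    m = table["model"].to_numpy()
    for row in range(n):
        for drug in (a[row], b[row]):
            pos = drug_pos.get(drug)
            if pos is not None:
                block[row, pos] = 1.0
        pos = model_pos.get(m[row])
        if pos is not None:
            block[row, pos] = 1.0
    return block


def _design(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    if model.kind in ("rf_features", "linear", "logistic"):
        return _feature_block(table, model.feature_columns)
    if model.kind == "rf_onehot":
        return _onehot_block(table, model.drug_vocab, model.model_vocab)
    if model.kind == "rf_concat":
        return np.hstack(
            [
                _feature_block(table, model.feature_columns),
                _onehot_block(table, model.drug_vocab, model.model_vocab),
            ]
        )
    raise ValueError(f"unknown model kind {model.kind!r}")


def _tuned_forest_fit(
    X: np.ndarray, y: np.ndarray, tuning: TuningConfig, seed: int
) -> tuple[RandomForestRegressor, dict, float, float]:
    """Random-search a forest; returns (fitted, params, best CV, default CV)."""
    if len(X) < tuning.k:
        raise ValueError(
            f"need at least k={tuning.k} rows for cross-validation, got {len(X)}"
        )
    tuning_seed, fold_seed, forest_seed = _derive_seeds(seed)
    candidates = [dict(DEFAULT_RF_PARAMS)] + [
        dict(p)
        for p in ParameterSampler(
            tuning.search_space, n_iter=tuning.n_iter, random_state=tuning_seed
        )
    ]
    folds = list(
        KFold(n_splits=tuning.k, shuffle=True, random_state=fold_seed).split(X)
    )
    scores = []
    for params in candidates:
        fold_scores = []
        for train_idx, test_idx in folds:
            forest = RandomForestRegressor(random_state=forest_seed, **params)
            forest.fit(X[train_idx], y[train_idx])
            fold_scores.append(forest.score(X[test_idx], y[test_idx]))
        scores.append(float(np.mean(fold_scores)))
    best = int(np.argmax(scores))  # ties resolve to the earliest candidate
    final = RandomForestRegressor(random_state=forest_seed, **candidates[best])
    final.fit(X, y)
    return final, candidates[best], scores[best], scores[0]


def _require_score(features: pd.DataFrame) -> np.ndarray:
    if "score" not in features.columns:
        raise SchemaError("feature table has no 'score' column to train on")
    return features["score"].to_numpy(dtype=float)


def fit_acda(
    features: pd.DataFrame, tuning: TuningConfig | None = None, seed: int = 0
) -> FittedModel:
    """Tuned random forest on the four monotherapy-derived features."""
    tuning = tuning or TuningConfig()
    y = _require_score(features)
    X = _feature_block(features, FEATURE_COLUMNS)
    forest, params, best, base = _tuned_forest_fit(X, y, tuning, seed)
    return FittedModel(
        method_tag="ACDA",
        kind="rf_features",
        estimator=forest,
        feature_columns=tuple(FEATURE_COLUMNS),
        hyperparams=params,
        seed=seed,
        cv_score_best=best,
        cv_score_default=base,
    )


def fit_cda(features: pd.DataFrame, mode: str = "auto") -> FittedModel:
    """The linear/logistic baseline on the same four features.

    ``mode='auto'`` selects logistic when the target takes exactly two
    values and linear otherwise (continuous harmonized synergy scores are
    regressed directly).
    """
    y = _require_score(features)
    X = _feature_block(features, FEATURE_COLUMNS)
    unique = np.unique(y)
    if mode == "auto":
        mode = "logistic" if len(unique) == 2 else "linear"
    if mode == "logistic":
        if len(unique) != 2:
            raise ModeError(
                f"logistic mode requires a binary target; found {len(unique)} "
                "distinct values"
            )
        est = LogisticRegression(max_iter=1000)
        est.fit(X, (y == unique.max()).astype(int))
        kind = "logistic"
    elif mode == "linear":
        est = LinearRegression()
        est.fit(X, y)
        kind = "linear"
    else:
        raise ModeError(f"unknown CDA mode {mode!r}")
    return FittedModel(
        method_tag="CDA",
        kind=kind,
        estimator=est,
        feature_columns=tuple(FEATURE_COLUMNS),
        hyperparams={"mode": mode},
    )


def fit_en(
    features: pd.DataFrame,
    seed: int = 0,
    drug_vocab: Sequence[str] | None = None,
    model_vocab: Sequence[str] | None = None,
    rf_params: dict | None = None,
) -> FittedModel:
    """Random forest on one-hot encoded drug and model names.

    Vocabularies default to the names observed in the training table and are
    frozen; unseen names at prediction time encode to all-zero blocks rather
    than raising.
    """
    y = _require_score(features)
    if drug_vocab is None:
        drug_vocab = sorted(set(features["drug_a"]) | set(features["drug_b"]))
    if model_vocab is None:
        model_vocab = sorted(set(features["model"]))
    params = dict(DEFAULT_RF_PARAMS, **(rf_params or {}))
    _, _, forest_seed = _derive_seeds(seed)
    X = _onehot_block(features, drug_vocab, model_vocab)
    forest = RandomForestRegressor(random_state=forest_seed, **params)
    forest.fit(X, y)
    return FittedModel(
        method_tag="EN",
        kind="rf_onehot",
        estimator=forest,
        feature_columns=(),
        drug_vocab=tuple(drug_vocab),
        model_vocab=tuple(model_vocab),
        hyperparams=params,
        seed=seed,
    )


def fit_en_acda(
    features: pd.DataFrame,
    tuning: TuningConfig | None = None,
    seed: int = 0,
    drug_vocab: Sequence[str] | None = None,
    model_vocab: Sequence[str] | None = None,
) -> FittedModel:
    """Tuned random forest on the ACDA features plus the EN one-hot design."""
    tuning = tuning or TuningConfig()
    y = _require_score(features)
    if drug_vocab is None:
        drug_vocab = sorted(set(features["drug_a"]) | set(features["drug_b"]))
    if model_vocab is None:
        model_vocab = sorted(set(features["model"]))
    X = np.hstack(
        [
            _feature_block(features, FEATURE_COLUMNS),
            _onehot_block(features, drug_vocab, model_vocab),
        ]
    )
    forest, params, best, base = _tuned_forest_fit(X, y, tuning, seed)
    return FittedModel(
        method_tag="EN-ACDA",
        kind="rf_concat",
        estimator=forest,
        feature_columns=tuple(FEATURE_COLUMNS),
        drug_vocab=tuple(drug_vocab),
        model_vocab=tuple(model_vocab),
        hyperparams=params,
        seed=seed,
        cv_score_best=best,
        cv_score_default=base,
    )


def predict(model: FittedModel, features: pd.DataFrame) -> np.ndarray:
    """One finite synergy prediction per feature-table row."""
    X = _design(model, features)
    if model.kind == "logistic":
        return model.estimator.predict_proba(X)[:, 1]
    return np.asarray(model.estimator.predict(X), dtype=float)


def consensus_average(
    pred_1: np.ndarray | pd.Series, pred_2: np.ndarray | pd.Series
) -> np.ndarray | pd.Series:
    """Elementwise mean of two aligned prediction vectors (ACDA-EN-ACDA)."""
    if isinstance(pred_1, pd.Series) and isinstance(pred_2, pd.Series):
        if not pred_1.index.equals(pred_2.index):
            raise AlignmentError("prediction vectors are keyed by different records")
        return (pred_1 + pred_2) / 2.0
    a, b = np.asarray(pred_1, dtype=float), np.asarray(pred_2, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"prediction lengths differ: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a fitted model (estimator, schema, hyperparameters, seed)."""
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path: str | Path) -> FittedModel:
    payload = joblib.load(path)
    return payload["model"]
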