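"""Pair-level cross-validation, recursive feature elimination, and the
boosted-tree regression harness.

Every splitting operation treats a direct/reverse mutation pair as one unit:
fold assignment is over pair ids, and a leakage guard asserts that no pair id
ever spans the train/validation boundary of any fold.  The default learner is
an XGBoost gradient-boosted tree regressor (L1/L2 regularised, native
missing-value handling); any scikit-learn-style regressor can be run through
the identical folds via the ``estimator_factory`` hook so model comparisons
share data splits exactly.

RFE removes exactly one feature per round: fit on the current set, record the
mean cross-validated R², rank by total-gain importance, drop the least
important feature (ties broken by removing the later registry column), and
repeat down to ``stop_size``.  The optimal subset is the remaining set at the
round with the highest mean R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBRegressor

from .evaluation import r_squared
from .features import FeatureTable

DEFAULT_XGB_PARAMS = {
    "n_estimators": 200,
    "learning_rate": 0.1,
    "max_depth": 6,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
    "reg_alpha": 0.1,
    "reg_lambda": 1.0,
    "tree_method": "hist",
    "n_jobs": 1,
}


class PairingError(ValueError):
    pass


@dataclass
class FoldScore:
    fold: int
    r2: float
    n_pairs: int


@dataclass
class RFERound:
    round_index: int
    mean_r2: float
    std_r2: float
    removed: str | None
    remaining_count: int


@dataclass
class RFETrace:
    rounds: list[RFERound]
    initial_features: list[str]
    removed_order: list[str]

    def features_at_round(self, round_index: int) -> list[str]:
        """Feature set evaluated at the given round (before its removal)."""
        dropped = set(self.removed_order[:round_index])
        return [f for f in self.initial_features if f not in dropped]

    @property
    def best_round(self) -> int:
        scores = [r.mean_r2 for r in self.rounds]
        return int(np.argmax(scores))

    @property
    def selected_features(self) -> list[str]:
        return self.features_at_round(self.best_round)


@dataclass
class TrainedRegressor:
    model: object
    feature_names: list[str]
    importances: dict[str, float]
    seed: int
    hyperparams: dict = field(default_factory=dict)


def _table_pair_ids(table: FeatureTable) -> pd.Series:
    if table.pair_ids is None or table.pair_ids.isna().any():
        raise PairingError("every row must carry a pair_id for pair-level operations")
    return table.pair_ids


def table_pair_folds(table: FeatureTable, k: int, seed: int) -> dict[str, int]:
    """Assign each pair id in the table to one of k folds (sizes differ ≤ 1)."""
    pair_ids = _table_pair_ids(table)
    unique = list(dict.fromkeys(pair_ids))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(unique):
        raise ValueError(f"k={k} exceeds number of pairs ({len(unique)})")
    counts = pair_ids.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()[:3]
        raise PairingError(f"unpaired rows for pair ids {bad}")
    rng = np.random.RandomState(seed)
    idx = np.arange(len(unique))
    rng.shuffle(idx)
    assignment: dict[str, int] = {}
    for fold, block in enumerate(np.array_split(idx, k)):
        for i in block:
            assignment[unique[i]] = fold
    return assignment


def _make_estimator(hyperparams: dict | None, seed: int):
    params = dict(DEFAULT_XGB_PARAMS)
    params.update(hyperparams or {})
    return XGBRegressor(random_state=seed, **params)


def crossval_pairlevel(
    table: FeatureTable,
    k: int = 20,
    seed: int = 0,
    hyperparams: dict | None = None,
    feature_subset: list[str] | None = None,
    estimator_factory=None,
    return_predictions: bool = False,
):
    """k-fold pair-level cross-validation scored by R² on each held-out fold.

    Returns ``(fold_scores, mean_r2, std_r2)``; with ``return_predictions``
    an out-of-fold prediction series is appended.  Folds with fewer than two
    pairs are rejected, and a leakage assertion verifies that no pair id
    appears on both sides of any fold.
    """
    folds = table_pair_folds(table, k, seed)
    pair_ids = _table_pair_ids(table)
    fold_of_row = pair_ids.map(folds)
    X = table.values[feature_subset] if feature_subset else table.values
    y = table.labels
    scores: list[FoldScore] = []
    oof = pd.Series(np.nan, index=table.values.index, name="prediction")
    for fold in range(k):
        val_mask = (fold_of_row == fold).to_numpy()
        train_pairs = set(pair_ids[~val_mask])
        val_pairs = set(pair_ids[val_mask])
        assert not (train_pairs & val_pairs), "pair id spans train and validation"
        if len(val_pairs) < 2:
            raise ValueError(f"fold {fold} holds fewer than two pairs")
        if estimator_factory is not None:
            est = estimator_factory(seed)
        else:
            est = _make_estimator(hyperparams, seed)
        est.fit(X[~val_mask], y[~val_mask])
        pred = est.predict(X[val_mask])
        oof[val_mask] = pred
        scores.append(
            FoldScore(fold=fold, r2=r_squared(pred, y[val_mask].to_numpy()),
                      n_pairs=len(val_pairs))
        )
    r2s = np.array([s.r2 for s in scores])
    if return_predictions:
        return scores, float(r2s.mean()), float(r2s.std()), oof
    return scores, float(r2s.mean()), float(r2s.std())


def train_regressor(
    table: FeatureTable,
    feature_subset: list[str] | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> TrainedRegressor:
    """Fit the gradient-boosted tree regressor on all rows of the table.

    Deterministic for a fixed seed; importance scores are total gain, with
    features the booster never used scored 0.
    """
    if feature_subset is not None and len(feature_subset) == 0:
        raise ValueError("feature subset must be non-empty")
    features = list(feature_subset) if feature_subset is not None else list(table.values.columns)
    if len(table) < 2:
        raise ValueError("need at least two rows to train")
    est = _make_estimator(hyperparams, seed)
    est.fit(table.values[features], table.labels)
    importances = _total_gain_importances(est, features)
    return TrainedRegressor(
        model=est,
        feature_names=list(features),
        importances=importances,
        seed=seed,
        hyperparams=dict(hyperparams or {}),
    )


def _total_gain_importances(est, features: list[str]) -> dict[str, float]:
    booster = est.get_booster()
    raw = booster.get_score(importance_type="total_gain")
    out = {}
    for i, name in enumerate(features):
        out[name] = float(raw.get(name, raw.get(f"f{i}", 0.0)))
    return out


def predict_ddg(
    model: TrainedRegressor, rows: pd.DataFrame | FeatureTable, strict: bool = False
) -> pd.Series:
    """Predict ΔΔG (kcal/mol) for feature rows, aligning columns by name.

    Extra columns are ignored.  Features the model needs but the rows lack
    are masked (NaN, handled natively by the tree learner) unless ``strict``.
    """
    df = rows.values if isinstance(rows, FeatureTable) else rows
    missing = [f for f in model.feature_names if f not in df.columns]
    if missing:
        if strict:
            raise KeyError(f"rows lack required model features: {missing[:5]}")
        df = df.copy()
        for f in missing:
            df[f] = np.nan
    aligned = df[model.feature_names]
    return pd.Series(model.model.predict(aligned), index=df.index, name="predicted_ddg")


def rfe_select(
    table: FeatureTable,
    k: int = 20,
    seed: int = 0,
    stop_size: int = 1,
    hyperparams: dict | None = None,
    feature_subset: list[str] | None = None,
) -> RFETrace:
    """Recursive feature elimination with pair-level cross-validated scoring.

    Per round: cross-validate the current feature set and record mean/std R²,
    fit once on all rows for total-gain importances, and remove the single
    least-important feature (ties broken by removing the later registry
    column).  Stops when ``stop_size`` features would remain un-scored.
    """
    current = list(feature_subset or table.values.columns)
    if len(current) < 2:
        raise ValueError("RFE needs at least two features")
    initial = list(current)
    rounds: list[RFERound] = []
    removed_order: list[str] = []
    stop_size = max(stop_size, 1)
    round_index = 0
    while len(current) > stop_size:
        _, mean_r2, std_r2 = crossval_pairlevel(
            table, k=k, seed=seed, hyperparams=hyperparams, feature_subset=current
        )
        fitted = train_regressor(table, current, hyperparams, seed)
        imps = fitted.importances
        min_imp = min(imps[f] for f in current)
        # ties: remove the feature latest in registry (column) order
        victim = max(
            (f for f in current if imps[f] == min_imp), key=current.index
        )
        current = [f for f in current if f != victim]
        removed_order.append(victim)
        rounds.append(
            RFERound(round_index, mean_r2, std_r2, victim, len(current))
        )
        round_index += 1
    return RFETrace(rounds=rounds, initial_features=initial, removed_order=removed_order)


@dataclass
class SearchTrial:
    params: dict
    mean_r2: float


def tune_hyperparameters(
    table: FeatureTable,
    search_space: dict[str, list],
    budget: int = 20,
    seed: int = 0,
    k: int = 20,
    feature_subset: list[str] | None = None,
    strategy=None,
) -> tuple[dict, list[SearchTrial]]:
    """Maximise mean pair-level cross-validated R² over a hyperparameter space.

    The default strategy is seeded random search over the listed candidate
    values; a smarter (e.g. Bayesian) search can be plugged in as
    ``strategy(search_space, budget, seed) -> iterable of param dicts``.
    Returns the best parameters and the full trial log.
    """
    if not search_space:
        raise ValueError("search space must not be empty")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if strategy is None:
        rng = np.random.RandomState(seed)
        candidates = [
            {name: values[rng.randint(len(values))] for name, values in search_space.items()}
            for _ in range(budget)
        ]
    else:
        candidates = list(strategy(search_space, budget, seed))[:budget]
    log: list[SearchTrial] = []
    for params in candidates:
        _, mean_r2, _ = crossval_pairlevel(
            table, k=k, seed=seed, hyperparams=params, feature_subset=feature_subset
        )
        log.append(SearchTrial(params=params, mean_r2=mean_r2))
    best = max(log, key=lambda t: t.mean_r2)
    return dict(best.params), log
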