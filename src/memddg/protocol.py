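"""Training and evaluation protocol for the ΔΔG regressor.

The regressor is a gradient-boosted decision-tree ensemble (XGBoost).
Model selection follows a randomized protocol: hyperparameter candidates
are drawn uniformly from a finite dictionary, each candidate is scored by
k-fold cross-validation, and the winner maximizes the Pearson correlation
coefficient (PCC) between experimental and pooled out-of-fold predicted
ΔΔG. Reported performance is the mean ± SD of the PCC over repeated
cross-validation runs with distinct fold seeds. Feature relevance is the
gain-based importance averaged over many fold models and normalized to
sum to one.

Everything is deterministic under a master seed: fold assignments,
hyperparameter draws, fitted ensembles and predictions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .curation import Mutation
from .features import FeatureSetId, FeatureSetSpec, FeatureTables, assemble_features, make_feature_spec

__all__ = [
    "DEFAULT_HYPERPARAMETER_SPACE",
    "DEFAULT_HYPERPARAMETERS",
    "CVConfig",
    "CVResult",
    "TrainedModel",
    "kfold_split",
    "cross_validate",
    "hyperparameter_search",
    "repeated_cv",
    "feature_importance",
    "fit_final",
    "predict_ddg",
    "pearson_cc",
]

#: Finite candidate dictionary for the randomized hyperparameter search.
DEFAULT_HYPERPARAMETER_SPACE: dict = {
    "n_estimators": [100, 200, 300, 500, 800],
    "max_depth": [3, 4, 5, 6, 8, 10],
    "learning_rate": [0.01, 0.03, 0.05, 0.1, 0.2],
    "subsample": [0.6, 0.7, 0.8, 0.9, 1.0],
    "colsample_bytree": [0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "reg_alpha": [0.0, 0.01, 0.1, 1.0],
    "reg_lambda": [0.5, 1.0, 2.0, 5.0],
    "min_child_weight": [1, 3, 5, 10],
}

#: Sensible defaults when no search is run.
DEFAULT_HYPERPARAMETERS: dict = {
    "n_estimators": 300,
    "max_depth": 6,
    "learning_rate": 0.05,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "reg_alpha": 0.0,
    "reg_lambda": 1.0,
    "min_child_weight": 1,
}


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and search settings.

    ``k`` is the fold count (5 or 10 in the reference protocol);
    ``n_search_iters`` the number of random hyperparameter draws;
    ``n_eval_iters`` the number of repeated CV runs for the reported
    mean ± SD; ``seed`` the master seed for all derived randomness.
    """

    k: int = 10
    n_search_iters: int = 1000
    n_eval_iters: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_search_iters < 1 or self.n_eval_iters < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass
class CVResult:
    """Pooled out-of-fold predictions and summary metrics of one CV run."""

    predictions: np.ndarray  # aligned to sample order, one prediction per sample
    y_true: np.ndarray
    pcc: float
    rmse: float
    fold_indices: list  # list of k test-index arrays


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; raises on constant input where it is undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def _make_regressor(hp: Mapping, seed: int, importance_type: str = "gain") -> XGBRegressor:
    return XGBRegressor(
        **dict(hp),
        random_state=int(seed) % (2**31 - 1),
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
        importance_type=importance_type,
    )


def kfold_split(n_samples: int, k: int, seed: int) -> list:
    """Shuffled k-fold partition of {0..n-1}; fold sizes differ by at most 1."""
    if k > n_samples:
        raise ValueError(f"k={k} exceeds sample count {n_samples}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31 - 1))
    return [test_idx.copy() for _, test_idx in splitter.split(np.zeros(n_samples))]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    hp: Optional[Mapping] = None,
    cvconfig: CVConfig = CVConfig(),
) -> CVResult:
    """One k-fold cross-validation run with pooled out-of-fold metrics.

    The model is refit k times; each sample is predicted exactly once while
    held out. PCC and RMSE are computed on the pooled prediction vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y are misaligned")
    if np.ptp(y) == 0:
        raise ValueError("target is constant; cross-validated PCC is undefined")
    hp = dict(hp) if hp is not None else dict(DEFAULT_HYPERPARAMETERS)
    folds = kfold_split(X.shape[0], cvconfig.k, cvconfig.seed)
    preds = np.full(X.shape[0], np.nan)
    all_idx = np.arange(X.shape[0])
    for test_idx in folds:
        train_mask = np.ones(X.shape[0], dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        assert np.intersect1d(train_idx, test_idx).size == 0, "train/test leakage"
        model = _make_regressor(hp, cvconfig.seed)
        model.fit(X[train_idx], y[train_idx])
        preds[test_idx] = model.predict(X[test_idx])
    assert not np.any(np.isnan(preds)), "some samples never predicted"
    return CVResult(
        predictions=preds,
        y_true=y.copy(),
        pcc=pearson_cc(y, preds),
        rmse=_rmse(y, preds),
        fold_indices=folds,
    )


def _draw_hp(space: Mapping, rng: np.random.Generator) -> dict:
    return {name: values[rng.integers(len(values))] for name, values in space.items()}


def hyperparameter_search(
    X: np.ndarray,
    y: np.ndarray,
    space: Optional[Mapping] = None,
    cvconfig: CVConfig = CVConfig(),
) -> tuple:
    """Randomized search: independent uniform draws scored by CV PCC.

    Draws are with replacement. The winner maximizes pooled out-of-fold
    PCC; ties break by lower RMSE, then by earlier draw, so the result is
    reproducible under a fixed seed. Returns ``(best_hp, best_CVResult)``.
    """
    space = dict(space) if space is not None else dict(DEFAULT_HYPERPARAMETER_SPACE)
    for name, values in space.items():
        if not values:
            raise ValueError(f"hyperparameter {name} has an empty candidate list")
    rng = np.random.default_rng(cvconfig.seed)
    best: tuple = None
    for it in range(cvconfig.n_search_iters):
        hp = _draw_hp(space, rng)
        result = cross_validate(X, y, hp, cvconfig)
        key = (-result.pcc, result.rmse, it)
        if best is None or key < best[0]:
            best = (key, hp, result)
    return best[1], best[2]


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    hp: Optional[Mapping] = None,
    cvconfig: CVConfig = CVConfig(),
) -> tuple:
    """Repeated k-fold CV with distinct derived fold seeds.

    Returns ``(mean_pcc, sd_pcc, best CVResult)`` over ``n_eval_iters``
    runs; SD is the sample (n−1) standard deviation.
    """
    pccs = []
    best: tuple = None
    for it in range(cvconfig.n_eval_iters):
        sub_seed = (cvconfig.seed * 1_000_003 + it) % (2**31 - 1)
        sub = CVConfig(k=cvconfig.k, n_search_iters=1, n_eval_iters=1, seed=sub_seed)
        result = cross_validate(X, y, hp, sub)
        pccs.append(result.pcc)
        if best is None or result.pcc > best[0]:
            best = (result.pcc, result)
    mean = float(np.mean(pccs))
    sd = float(np.std(pccs, ddof=1)) if len(pccs) > 1 else 0.0
    return mean, sd, best[1]


def feature_importance(
    X: np.ndarray,
    y: np.ndarray,
    hp: Optional[Mapping] = None,
    n_repeats: int = 100,
    k: int = 10,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    groups: Optional[Mapping[str, str]] = None,
) -> tuple:
    """Average importance over repeated k-fold fits.

    Importance is the total split gain a feature contributes across the
    ensemble (its cumulative reduction of the training loss), which is the
    additive measure appropriate for class-level roll-ups. Every fold model
    of every repeat contributes its importance vector; the average is
    normalized to sum to 1. Returns ``(ranked, group_rollup)``
    where ``ranked`` is a descending list of (feature, mean importance) and
    ``group_rollup`` sums importance per feature class when ``groups`` maps
    feature name → class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    hp = dict(hp) if hp is not None else dict(DEFAULT_HYPERPARAMETERS)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    total = np.zeros(X.shape[1])
    n_models = 0
    all_idx = np.arange(X.shape[0])
    for rep in range(n_repeats):
        rep_seed = (seed * 7_654_321 + rep) % (2**31 - 1)
        for test_idx in kfold_split(X.shape[0], k, rep_seed):
            train_mask = np.ones(X.shape[0], dtype=bool)
            train_mask[test_idx] = False
            model = _make_regressor(hp, rep_seed, importance_type="total_gain")
            model.fit(X[all_idx[train_mask]], y[all_idx[train_mask]])
            total += model.feature_importances_
            n_models += 1
    mean_imp = total / n_models
    s = mean_imp.sum()
    if s > 0:
        mean_imp = mean_imp / s
    ranked = sorted(zip(feature_names, mean_imp), key=lambda t: -t[1])
    rollup: dict = {}
    if groups:
        for name, imp in zip(feature_names, mean_imp):
            g = groups.get(name, "other")
            rollup[g] = rollup.get(g, 0.0) + float(imp)
    return ranked, rollup


@dataclass
class TrainedModel:
    """A fitted ensemble bound to its feature layout.

    The layout hash makes prediction refuse inputs assembled under a
    different feature order, so a stale or foreign matrix cannot silently
    produce numbers.
    """

    regressor: XGBRegressor
    spec: FeatureSetSpec
    hyperparameters: dict
    seed: int
    k: int
    feature_order_hash: str
    metadata: dict = field(default_factory=dict)
    tables: Optional[FeatureTables] = None

    @staticmethod
    def hash_spec(spec: FeatureSetSpec) -> str:
        return hashlib.sha256("\t".join(spec.names).encode()).hexdigest()

    def predict_matrix(self, X: np.ndarray, spec: Optional[FeatureSetSpec] = None) -> np.ndarray:
        if spec is not None and self.hash_spec(spec) != self.feature_order_hash:
            raise ValueError("feature layout mismatch: refusing to predict")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.spec.expected_length:
            raise ValueError(
                f"expected {self.spec.expected_length} features, got {X.shape[1]}"
            )
        return self.regressor.predict(X)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        if cls.hash_spec(model.spec) != model.feature_order_hash:
            raise ValueError("feature-order hash mismatch in loaded artifact")
        return model


def fit_final(
    X: np.ndarray,
    y: np.ndarray,
    hp: Optional[Mapping] = None,
    spec: Optional[FeatureSetSpec] = None,
    seed: int = 0,
    k: int = 10,
    tables: Optional[FeatureTables] = None,
    metadata: Optional[dict] = None,
) -> TrainedModel:
    """Fit the ensemble on all rows and bundle it with its feature layout."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    spec = spec or make_feature_spec(FeatureSetId.ONLY_10_PLUS)
    if X.shape[1] != spec.expected_length:
        raise ValueError("feature matrix width disagrees with the feature-set layout")
    hp = dict(hp) if hp is not None else dict(DEFAULT_HYPERPARAMETERS)
    model = _make_regressor(hp, seed)
    model.fit(X, y)
    return TrainedModel(
        regressor=model,
        spec=spec,
        hyperparameters=hp,
        seed=seed,
        k=k,
        feature_order_hash=TrainedModel.hash_spec(spec),
        metadata=dict(metadata or {}),
        tables=tables,
    )


def predict_ddg(
    model: TrainedModel,
    interacting_sequence: str,
    mutating_sequence: str,
    mutation: Mutation,
    pssm_pair: tuple,
) -> float:
    """Predict ΔΔG (kcal/mol) for one mutation; positive = destabilizing.

    ``pssm_pair`` is ``(mutating_pssm, interacting_pssm)``. The stated
    wild-type residue must match the mutating sequence at the mutation
    position, and the PSSM must belong to that sequence.
    """
    from .curation import AffinityRecord

    record = AffinityRecord(
        complex_id="query",
        partner_a_id="mutating",
        partner_b_id="interacting",
        mutated_partner="A",
        mutation=mutation,
        ddg=None,
    )
    sequences = {"mutating": mutating_sequence, "interacting": interacting_sequence}
    fv = assemble_features(record, sequences, pssm_pair, model.spec, model.tables)
    return float(model.predict_matrix(fv.values)[0])


def training_report(
    best_hp: Mapping, best_result: CVResult, mean_pcc: float, sd_pcc: float, cvconfig: CVConfig
) -> dict:
    """JSON-serializable summary of a training run."""
    return {
        "k": cvconfig.k,
        "seed": cvconfig.seed,
        "n_search_iters": cvconfig.n_search_iters,
        "n_eval_iters": cvconfig.n_eval_iters,
        "best_hyperparameters": dict(best_hp),
        "best_pcc": best_result.pcc,
        "best_rmse": best_result.rmse,
        "mean_pcc": mean_pcc,
        "sd_pcc": sd_pcc,
    }
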