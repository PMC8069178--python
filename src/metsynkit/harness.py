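"""Nested cross-validated gradient-boosted-tree classification.

The protocol: over ``n_iterations`` structured iterations, append a couple
of iid standard-normal "sanity" columns to the predictors, split the cohort
into a stratified 80/20 train/test partition, tune boosted-tree
hyperparameters by inner 5-fold cross-validation on the training split
(maximizing held-out AUC), refit on the full training split, and record the
test-split AUC plus per-feature gain importances. The mean ± sd of the
per-iteration AUCs is the model result; importances are aggregated as the
across-iteration mean, with the fraction of iterations in which a feature
entered the per-iteration top-k reported as its selection frequency. The
sanity columns calibrate believability: a real feature whose aggregate rank
does not beat random noise should not be interpreted.

The learner is defined by contract (fit / predict-probability / per-feature
importance); XGBoost's gradient-boosted trees are the default
implementation. Everything is deterministic given the base seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

__all__ = ["CVConfig", "NestedCVResult", "NestedCVClassifier", "run_nested_cv",
           "select_top_features", "rerun_on_subset", "sanity_report",
           "DEFAULT_GRID", "REDUCED_GRID"]

#: Hyperparameter grid searched by default in the inner loop.
DEFAULT_GRID = {
    "max_depth": [2, 3, 4],
    "learning_rate": [0.05, 0.1, 0.3],
    "n_estimators": [50, 100, 200],
    "subsample": [0.8, 1.0],
}

#: Small grid for desk-scale runs; keeps the tuning step meaningful while
#: fitting the full 100-iteration protocol on a single CPU.
REDUCED_GRID = {
    "max_depth": [2, 3],
    "learning_rate": [0.3],
    "n_estimators": [30],
    "subsample": [1.0],
}

SANITY_PREFIX = "__sanity_"


@dataclass
class CVConfig:
    """Protocol settings for the nested cross-validation harness."""

    n_iterations: int = 100
    test_fraction: float = 0.20
    inner_folds: int = 5
    n_sanity_features: int = 2
    top_k: int = 20
    param_grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    base_seed: int = 0
    max_bin: int = 32        # histogram bins for the tree builder

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be at least 2")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


@dataclass
class NestedCVResult:
    """Aggregated outcome of one nested-CV run."""

    per_iteration_auc: np.ndarray
    mean_auc: float
    sd_auc: float
    feature_importance: pd.DataFrame  # index feature id: importance, frequency, is_sanity
    sanity_flags: np.ndarray          # per iteration: any sanity feature in top_k
    sanity_fraction: float
    top_features: list
    chosen_params: list

    def to_dict(self) -> dict:
        feats = self.feature_importance
        real = feats[~feats["is_sanity"]]
        return {
            "per_iteration_auc": [float(a) for a in self.per_iteration_auc],
            "mean_auc": float(self.mean_auc),
            "sd_auc": float(self.sd_auc),
            "features": [
                {"id": str(i), "importance": float(row["importance"]),
                 "frequency": float(row["frequency"])}
                for i, row in real.iterrows()
            ],
            "top_features": [str(f) for f in self.top_features],
            "sanity_fraction": float(self.sanity_fraction),
        }


class NestedCVClassifier(BaseEstimator):
    """sklearn-style estimator wrapping the nested-CV protocol.

    ``fit`` runs the full iterated protocol and exposes the aggregate as
    fitted attributes (``mean_auc_``, ``feature_importances_``,
    ``top_features_``, ...); ``predict_proba`` uses a final model refit on
    all data with the modal chosen hyperparameters, so the object also
    behaves as an ordinary classifier after fitting.
    """

    def __init__(self, n_iterations=100, test_fraction=0.20, inner_folds=5,
                 n_sanity_features=2, top_k=20, param_grid=None, base_seed=0,
                 max_bin=32):
        self.n_iterations = n_iterations
        self.test_fraction = test_fraction
        self.inner_folds = inner_folds
        self.n_sanity_features = n_sanity_features
        self.top_k = top_k
        self.param_grid = param_grid
        self.base_seed = base_seed
        self.max_bin = max_bin

    # -- learner contract ----------------------------------------------------

    def _make_learner(self, params: dict, seed: int) -> XGBClassifier:
        return XGBClassifier(
            tree_method="hist", max_bin=self.max_bin, n_jobs=1, verbosity=0,
            eval_metric="logloss", importance_type="gain",
            random_state=seed, **params,
        )

    # -- protocol ------------------------------------------------------------

    def _config(self) -> CVConfig:
        grid = self.param_grid if self.param_grid is not None else dict(DEFAULT_GRID)
        return CVConfig(self.n_iterations, self.test_fraction, self.inner_folds,
                        self.n_sanity_features, self.top_k, grid,
                        self.base_seed, self.max_bin)

    def fit(self, X, y):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=np.float32)
        else:
            Xv = np.asarray(X, dtype=np.float32)
            names = [f"x{j}" for j in range(Xv.shape[1])]
        y = np.asarray(y)
        if np.isnan(Xv).any():
            raise ValueError("X must have no missing values")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError(f"need a binary label, got {classes.size} classes")
        if Xv.shape[0] < 10:
            raise ValueError("need at least 10 samples")
        if counts.min() < cfg.inner_folds:
            raise ValueError("fewer samples in a class than inner folds")
        if cfg.top_k > Xv.shape[1]:
            raise ValueError("top_k exceeds the number of real features")
        yb = (y == classes[1]).astype(int)

        n, m = Xv.shape
        k_all = m + cfg.n_sanity_features
        all_names = names + [f"{SANITY_PREFIX}{j}" for j in range(cfg.n_sanity_features)]
        grid = list(ParameterGrid(cfg.param_grid))

        aucs = np.empty(cfg.n_iterations)
        importance_sum = np.zeros(k_all)
        topk_counts = np.zeros(k_all)
        sanity_flags = np.zeros(cfg.n_iterations, dtype=bool)
        chosen = []

        for it in range(cfg.n_iterations):
            seed = cfg.base_seed + it
            rng = np.random.default_rng(seed)
            if cfg.n_sanity_features:
                sanity = rng.standard_normal((n, cfg.n_sanity_features)).astype(np.float32)
                Xi = np.hstack([Xv, sanity])
            else:
                Xi = Xv
            idx_train, idx_test = train_test_split(
                np.arange(n), test_size=cfg.test_fraction, stratify=yb,
                random_state=seed)
            Xtr, ytr = Xi[idx_train], yb[idx_train]
            Xte, yte = Xi[idx_test], yb[idx_test]

            best_params, best_score = grid[0], -np.inf
            if len(grid) > 1:
                skf = StratifiedKFold(cfg.inner_folds, shuffle=True, random_state=seed)
                folds = list(skf.split(Xtr, ytr))
                for params in grid:
                    fold_aucs = []
                    for tr, va in folds:
                        model = self._make_learner(params, seed)
                        model.fit(Xtr[tr], ytr[tr])
                        proba = model.predict_proba(Xtr[va])[:, 1]
                        fold_aucs.append(roc_auc_score(ytr[va], proba))
                    score = float(np.mean(fold_aucs))
                    if score > best_score:
                        best_score, best_params = score, params

            model = self._make_learner(best_params, seed)
            model.fit(Xtr, ytr)
            aucs[it] = roc_auc_score(yte, model.predict_proba(Xte)[:, 1])
            chosen.append(dict(best_params))

            imp = np.asarray(model.feature_importances_, dtype=float)
            importance_sum += imp
            order = np.argsort(-imp, kind="stable")
            top = order[: cfg.top_k]
            top = top[imp[top] > 0]  # zero importance never counts as selected
            topk_counts[top] += 1
            if cfg.n_sanity_features:
                sanity_flags[it] = bool((top >= m).any())

        mean_imp = importance_sum / cfg.n_iterations
        freq = topk_counts / cfg.n_iterations
        feats = pd.DataFrame(
            {"importance": mean_imp, "frequency": freq,
             "is_sanity": [i >= m for i in range(k_all)]},
            index=pd.Index(all_names, name="feature"),
        )

        self.classes_ = classes
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = m
        self.per_iteration_auc_ = aucs
        self.mean_auc_ = float(aucs.mean())
        self.sd_auc_ = float(aucs.std(ddof=1)) if cfg.n_iterations > 1 else 0.0
        self.feature_importances_frame_ = feats
        self.sanity_flags_ = sanity_flags
        self.sanity_fraction_ = float(sanity_flags.mean())
        self.chosen_params_ = chosen
        self.top_features_ = _rank_features(feats, min(cfg.top_k, m))

        # final convenience model on all data with the modal hyperparameters
        modal = max({tuple(sorted(c.items())) for c in chosen},
                    key=lambda t: sum(tuple(sorted(c.items())) == t for c in chosen))
        self._final_model_ = self._make_learner(dict(modal), cfg.base_seed)
        self._final_model_.fit(Xv, yb)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_final_model_")
        Xv = X.to_numpy(dtype=np.float32) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=np.float32)
        return self._final_model_.predict_proba(Xv)

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba >= 0.5, self.classes_[1], self.classes_[0])

    def result_(self) -> NestedCVResult:
        check_is_fitted(self, "per_iteration_auc_")
        return NestedCVResult(
            per_iteration_auc=self.per_iteration_auc_,
            mean_auc=self.mean_auc_, sd_auc=self.sd_auc_,
            feature_importance=self.feature_importances_frame_,
            sanity_flags=self.sanity_flags_,
            sanity_fraction=self.sanity_fraction_,
            top_features=self.top_features_,
            chosen_params=self.chosen_params_,
        )


def _rank_features(feats: pd.DataFrame, k: int) -> list:
    """Deterministic ranking of real features: importance desc, then
    selection frequency desc, then lexicographic feature id."""
    real = feats[~feats["is_sanity"]]
    order = sorted(real.index,
                   key=lambda f: (-real.at[f, "importance"],
                                  -real.at[f, "frequency"], str(f)))
    return order[:k]


def run_nested_cv(X, y, config: CVConfig | None = None) -> NestedCVResult:
    """Run the full nested-CV protocol; see :class:`NestedCVClassifier`."""
    cfg = config or CVConfig()
    est = NestedCVClassifier(
        n_iterations=cfg.n_iterations, test_fraction=cfg.test_fraction,
        inner_folds=cfg.inner_folds, n_sanity_features=cfg.n_sanity_features,
        top_k=cfg.top_k, param_grid=cfg.param_grid, base_seed=cfg.base_seed,
        max_bin=cfg.max_bin)
    est.fit(X, y)
    return est.result_()


def select_top_features(result: NestedCVResult, k: int) -> list:
    """Top k real (non-sanity) features by aggregated importance."""
    n_real = int((~result.feature_importance["is_sanity"]).sum())
    if k > n_real:
        raise ValueError(f"k={k} exceeds the {n_real} real features")
    return _rank_features(result.feature_importance, k)


def rerun_on_subset(X, y, features, config: CVConfig | None = None) -> NestedCVResult:
    """Re-run the identical protocol on a feature subset."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in features if f not in X.columns]
        if missing:
            raise KeyError(f"features not in X: {missing[:5]}")
        Xs = X[list(features)]
    else:
        Xs = np.asarray(X)[:, list(features)]
    return run_nested_cv(Xs, y, config)


def sanity_report(result: NestedCVResult, threshold: float = 0.05) -> dict:
    """Fraction of iterations in which a sanity feature reached the top-k."""
    frac = float(result.sanity_fraction)
    return {"sanity_fraction": frac, "warning": frac > threshold}
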