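"""Downstream prognostic utility: TSTR and TRTR AUROC.

The downstream task is the predefined binary classification on the core
variables.  Utility of a synthetic dataset is train-synthetic-test-real
(TSTR): a classifier is trained on each synthetic replicate and evaluated by
AUROC on the fixed real holdout, then averaged across replicates.
Train-real-test-real (TRTR) on the same split is the reference point.  Two
learners are supported: a gradient-boosted tree ensemble (LightGBM) with
hyperparameters chosen by 5-fold cross-validated AUROC, and a small
multilayer perceptron (16–16–1 with sigmoid output) regularized by
validation-based early stopping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.compose import ColumnTransformer
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .errors import ValidationError

__all__ = [
    "TaskSpec",
    "UtilityReport",
    "DEFAULT_GBM_GRID",
    "train_gbm",
    "train_mlp",
    "evaluate_tstr",
    "evaluate_trtr",
    "holdout_auroc",
]

logger = logging.getLogger("tabhallu.utility")

DEFAULT_GBM_GRID = {
    "learning_rate": [0.05, 0.1],
    "num_leaves": [15, 31, 63],
    "n_estimators": [100, 300],
}


@dataclass(frozen=True)
class TaskSpec:
    outcome_name: str
    feature_names: tuple[str, ...]
    positive_level: object = 1

    def validate(self, table: pd.DataFrame) -> None:
        missing = set(self.feature_names) - set(table.columns)
        if missing:
            raise ValidationError(f"task features absent from table: {sorted(missing)}")
        if self.outcome_name not in table.columns:
            raise ValidationError(f"outcome {self.outcome_name!r} absent from table")


@dataclass
class UtilityReport:
    learner: str
    tstr_per_replicate: list[float]  # NaN where a replicate was degenerate
    tstr_mean: float
    trtr: float = float("nan")

    @property
    def auroc_delta(self) -> float:
        return self.trtr - self.tstr_mean


def _xy(table: pd.DataFrame, task: TaskSpec) -> tuple[pd.DataFrame, np.ndarray]:
    task.validate(table)
    y = (table[task.outcome_name] == task.positive_level).to_numpy(dtype=int)
    return table[list(task.feature_names)], y


def _feature_kinds(X: pd.DataFrame) -> tuple[list[str], list[str]]:
    cat = [c for c in X.columns if not pd.api.types.is_numeric_dtype(X[c])]
    num = [c for c in X.columns if c not in cat]
    return cat, num


def _gbm_matrix(X: pd.DataFrame, categories: dict[str, pd.Index] | None = None):
    """Integer-code categoricals against fixed level sets (missing/unseen -> -1),
    leaving numerics (with NaN) to LightGBM's native handling."""
    cat, _num = _feature_kinds(X)
    if categories is None:
        categories = {c: pd.Index(pd.unique(X[c].dropna())) for c in cat}
    out = X.copy()
    for c in cat:
        out[c] = pd.Categorical(X[c], categories=categories[c]).codes
        out[c] = out[c].astype("int32")
    return out, cat, categories


def _check_binary(y: np.ndarray, where: str) -> None:
    if len(np.unique(y)) < 2:
        level = int(y[0]) if len(y) else None
        raise ValidationError(
            f"{where}: outcome has a single class (level {level}); cannot train")


def train_gbm(train_table: pd.DataFrame, task: TaskSpec, cv_folds: int = 5,
              grid: dict | None = None, seed: int = 0):
    """LightGBM classifier; hyperparameters picked by mean CV AUROC over the
    grid (skipped when the grid has a single combination), then refit on all
    training rows.  Returns a fitted predictor with ``selected_params_``."""
    X, y = _xy(train_table, task)
    _check_binary(y, "train_gbm")
    grid = grid if grid is not None else DEFAULT_GBM_GRID
    Xm, cat_cols, categories = _gbm_matrix(X)

    from itertools import product
    keys = list(grid)
    combos = [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]

    def make(params):
        return LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1, **params)

    if len(combos) == 1:
        best = combos[0]
    else:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(Xm, y))
        scores = []
        for params in combos:
            aucs = []
            for tr, va in folds:
                clf = make(params)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(Xm.iloc[tr], y[tr],
                            categorical_feature=cat_cols or "auto")
                aucs.append(roc_auc_score(y[va], clf.predict_proba(Xm.iloc[va])[:, 1]))
            scores.append(float(np.mean(aucs)))
        best = combos[int(np.argmax(scores))]

    clf = make(best)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xm, y, categorical_feature=cat_cols or "auto")
    clf.selected_params_ = best
    clf._tabhallu_categories = categories
    clf._tabhallu_task = task
    return clf


def train_mlp(train_table: pd.DataFrame, task: TaskSpec, seed: int = 0):
    """16–16–1 multilayer perceptron with sigmoid output.

    Categoricals are one-hot encoded (missing as its own category), numerics
    median-imputed with an indicator and standardized.  Overfitting is
    controlled by early stopping on a 10% validation split rather than by
    extensive tuning.
    """
    X, y = _xy(train_table, task)
    _check_binary(y, "train_mlp")
    cat, num = _feature_kinds(X)
    transformers = []
    if cat:
        transformers.append(("cat", Pipeline([
            ("imp", SimpleImputer(strategy="constant", fill_value="__MISSING__")),
            ("oh", OneHotEncoder(handle_unknown="ignore", sparse_output=False)),
        ]), cat))
    if num:
        transformers.append(("num", Pipeline([
            ("imp", SimpleImputer(strategy="median", add_indicator=True)),
            ("sc", StandardScaler()),
        ]), num))
    pipe = Pipeline([
        ("prep", ColumnTransformer(transformers)),
        ("mlp", MLPClassifier(hidden_layer_sizes=(16, 16), activation="relu",
                              alpha=1e-4, batch_size=min(256, max(8, len(X) // 4)),
                              max_iter=100, early_stopping=True,
                              validation_fraction=0.1, n_iter_no_change=10,
                              random_state=seed)),
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X, y)
    pipe._tabhallu_task = task
    return pipe


_LEARNERS = {"gbm": train_gbm, "mlp": train_mlp}


def holdout_auroc(model, holdout: pd.DataFrame, task: TaskSpec) -> float:
    """AUROC (Mann–Whitney, ties averaged) of ``model`` on the holdout."""
    X, y = _xy(holdout, task)
    _check_binary(y, "holdout")
    if hasattr(model, "_tabhallu_categories"):
        X, _, _ = _gbm_matrix(X, model._tabhallu_categories)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = model.predict_proba(X)[:, 1]
    return float(roc_auc_score(y, p))


def _train_one(learner: str, table: pd.DataFrame, task: TaskSpec, seed: int,
               gbm_grid: dict | None, cv_folds: int):
    if learner == "gbm":
        return train_gbm(table, task, cv_folds=cv_folds, grid=gbm_grid, seed=seed)
    if learner == "mlp":
        return train_mlp(table, task, seed=seed)
    raise ValidationError(f"unknown learner {learner!r}")


def evaluate_tstr(replicates, holdout: pd.DataFrame, task: TaskSpec,
                  learner: str = "gbm", seed: int = 0,
                  gbm_grid: dict | None = None, cv_folds: int = 5) -> UtilityReport:
    """Train one classifier per synthetic replicate, score each on the real
    holdout, and report per-replicate AUROCs and their mean.  Replicates with
    a single-class outcome are recorded as NaN and excluded from the mean."""
    reps = replicates.replicates if hasattr(replicates, "replicates") else list(replicates)
    if not reps:
        raise ValidationError("no replicates supplied")
    aucs = []
    for r, rep in enumerate(reps):
        try:
            model = _train_one(learner, rep, task, seed, gbm_grid, cv_folds)
            aucs.append(holdout_auroc(model, holdout, task))
        except ValidationError as exc:
            logger.warning("replicate %d skipped: %s", r, exc)
            aucs.append(float("nan"))
    valid = [a for a in aucs if not np.isnan(a)]
    mean = float(np.mean(valid)) if valid else float("nan")
    return UtilityReport(learner=learner, tstr_per_replicate=aucs, tstr_mean=mean)


def evaluate_trtr(train: pd.DataFrame, holdout: pd.DataFrame, task: TaskSpec,
                  learner: str = "gbm", extra_splits: int = 0,
                  population: pd.DataFrame | None = None, seed: int = 0,
                  gbm_grid: dict | None = None, cv_folds: int = 5):
    """TRTR AUROC on the fixed split.  With ``extra_splits`` > 0 (and the full
    population table supplied) the population is re-split that many times and
    the AUROC distribution is returned alongside, to check sensitivity to the
    particular partition."""
    model = _train_one(learner, train, task, seed, gbm_grid, cv_folds)
    auroc = holdout_auroc(model, holdout, task)
    if extra_splits <= 0:
        return auroc
    if population is None:
        raise ValidationError("extra_splits requires the full population table")
    rng = np.random.default_rng(seed)
    n_train, n_hold = len(train), len(holdout)
    spread = []
    for s in range(extra_splits):
        perm = rng.permutation(len(population))
        tr = population.iloc[perm[:n_train]]
        ho = population.iloc[perm[n_train:n_train + n_hold]]
        m = _train_one(learner, tr, task, int(rng.integers(2**31 - 1)),
                       gbm_grid, cv_folds)
        spread.append(holdout_auroc(m, ho, task))
    return auroc, spread
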