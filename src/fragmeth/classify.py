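"""Two-class random-forest model on rho features with the top-r decision rule.

The model is y^i ~ [rho^i_AA ... rho^i_TT] with y in {0, 1}. Training is done
on a class-balanced set obtained by undersampling the majority (typically
unmethylated) class, so the forest's implied priors are 0.5/0.5. At predict
time the forest reports the posterior probability of methylation as the
average vote over its trees; islands are ranked by posterior and the top r
fraction (r = expected genome-wide fraction of methylated islands, supplied
or estimated from training labels) is called methylated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (average_precision_score, confusion_matrix,
                             precision_recall_curve, roc_auc_score, roc_curve)
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold

from .features import FEATURE_COLUMNS
from .labels import IslandLabel

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = 1

DEFAULT_HYPERPARAMS: Dict = {
    "n_estimators": 500,
    "max_depth": None,
    "max_features": "sqrt",
    "min_samples_leaf": 1,
}

#: small documented grid for optional hyperparameter search
DEFAULT_GRID: Dict[str, list] = {
    "n_estimators": [100, 500],
    "min_samples_leaf": [1, 5],
}


@dataclass
class ModelBundle:
    """A trained forest plus the metadata needed to apply it safely."""

    forest: RandomForestClassifier
    feature_names: Tuple[str, ...]
    metadata: Dict

    def save(self, path) -> None:
        joblib.dump({"format_version": BUNDLE_FORMAT_VERSION,
                     "forest": self.forest,
                     "feature_names": self.feature_names,
                     "metadata": self.metadata}, path)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        payload = joblib.load(path)
        if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ValueError(f"unsupported model bundle version in {path}")
        return cls(payload["forest"], tuple(payload["feature_names"]),
                   payload["metadata"])


def make_dataset(features: pd.DataFrame, labels: Sequence[IslandLabel],
                 sample: str = "sample") -> pd.DataFrame:
    """Join the rho table with definite labels into a training table.

    Keeps only islands with y in {0, 1}; island ids must be unique.
    """
    label_map = {l.island_id: l.y for l in labels if l.y in (0, 1)}
    if features["island_id"].duplicated().any():
        raise ValueError("duplicate island ids in feature table")
    dataset = features[features["island_id"].isin(label_map)].copy()
    dataset["y"] = dataset["island_id"].map(label_map).astype(int)
    dataset.attrs["sample"] = sample
    return dataset.reset_index(drop=True)


def balance_by_undersampling(dataset: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Downsample the majority class (uniformly, without replacement) to the
    minority class size. Deterministic given the seed."""
    classes = dataset["y"].value_counts()
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance")
    minority = classes.idxmin()
    n_keep = classes.min()
    rng = np.random.default_rng(seed)
    parts = []
    for cls, group in dataset.groupby("y", sort=True):
        if cls == minority or len(group) == n_keep:
            parts.append(group)
        else:
            idx = rng.choice(group.index.to_numpy(), size=n_keep, replace=False)
            parts.append(group.loc[np.sort(idx)])
    balanced = pd.concat(parts).sort_index().reset_index(drop=True)
    balanced.attrs.update(dataset.attrs)
    return balanced


def train_forest(dataset: pd.DataFrame, seed: int,
                 hyperparams: Optional[Dict] = None,
                 grid: Optional[Dict[str, list]] = None,
                 grid_cv: int = 5) -> ModelBundle:
    """Fit the random forest on a (balanced) training table.

    With ``grid`` given, a cross-validated grid search is run on the training
    split only and the best setting refit. Reproducible given ``seed``.
    """
    y = dataset["y"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = dataset.loc[:, list(FEATURE_COLUMNS)].to_numpy()
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    forest = RandomForestClassifier(random_state=seed, **params)
    chosen = dict(params)
    if grid:
        search = GridSearchCV(forest, grid, cv=grid_cv, scoring="balanced_accuracy")
        search.fit(X, y)
        forest = search.best_estimator_
        chosen.update(search.best_params_)
        logger.info("grid search selected %s", search.best_params_)
    else:
        forest.fit(X, y)
    counts = dict(zip(*np.unique(y, return_counts=True)))
    metadata = {
        "seed": seed,
        "hyperparams": chosen,
        "class_counts": {int(k): int(v) for k, v in counts.items()},
        "balanced_priors": "trained on balanced classes; implied priors 0.5/0.5",
        "sample": dataset.attrs.get("sample", "unknown"),
    }
    return ModelBundle(forest, FEATURE_COLUMNS, metadata)


def predict_posteriors(model: ModelBundle, features: pd.DataFrame) -> pd.DataFrame:
    """Posterior P(methylated) per island: the average tree vote.

    Returns a table island_id/chrom/start/posterior (chrom/start retained
    when present, for deterministic tie-breaking downstream).
    """
    missing = set(model.feature_names) - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    X = features.loc[:, list(model.feature_names)].to_numpy()
    class_index = list(model.forest.classes_).index(1)
    posterior = model.forest.predict_proba(X)[:, class_index]
    out = pd.DataFrame({"island_id": features["island_id"], "posterior": posterior})
    for col in ("chrom", "start"):
        if col in features.columns:
            out[col] = features[col].to_numpy()
    return out


def apply_top_r(predictions: pd.DataFrame, r: float) -> pd.DataFrame:
    """Hard labels from posterior ranking: the top round(r*K) islands are
    methylated, the remaining 1-r fraction unmethylated.

    Ties in the posterior are broken by (chrom, start, island_id) for
    determinism. round() is round-half-up of r*K.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    k_total = len(predictions)
    n_meth = int(np.floor(r * k_total + 0.5))
    sort_cols = ["posterior"]
    ascending = [False]
    for col in ("chrom", "start", "island_id"):
        if col in predictions.columns:
            sort_cols.append(col)
            ascending.append(True)
    ranked = predictions.sort_values(sort_cols, ascending=ascending, kind="mergesort")
    labels = np.zeros(k_total, dtype=int)
    labels[:n_meth] = 1
    ranked = ranked.assign(label=labels)
    return ranked.set_index("island_id").loc[predictions["island_id"]].reset_index()


def evaluate(y_true: Sequence[int], posteriors: Sequence[float],
             y_pred: Sequence[int]) -> Dict:
    """Evaluation metrics over islands with known truth.

    Macro-averaged accuracy is the unweighted mean of the two per-class
    accuracies; ROC/PR curves and their summary areas are computed from the
    posteriors. Raises when a truth class is absent (macro accuracy would be
    undefined).
    """
    y_true = np.asarray(y_true, dtype=int)
    posteriors = np.asarray(posteriors, dtype=float)
    y_pred = np.asarray(y_pred, dtype=int)
    if len({0, 1} - set(np.unique(y_true))) > 0:
        raise ValueError("both truth classes must be present for evaluation")
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    per_class = cm.diagonal() / cm.sum(axis=1)
    fpr, tpr, _ = roc_curve(y_true, posteriors)
    precision, recall, _ = precision_recall_curve(y_true, posteriors)
    return {
        "macro_accuracy": float(per_class.mean()),
        "per_class_accuracy": {"unmethylated": float(per_class[0]),
                               "methylated": float(per_class[1])},
        "auc_roc": float(roc_auc_score(y_true, posteriors)),
        "average_precision": float(average_precision_score(y_true, posteriors)),
        "confusion_matrix": cm.tolist(),
        "roc_curve": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        "pr_curve": {"precision": precision.tolist(), "recall": recall.tolist()},
    }


def cross_validate(dataset: pd.DataFrame, k: int = 10, seed: int = 0,
                   r: Optional[float] = None,
                   hyperparams: Optional[Dict] = None) -> Dict:
    """Stratified k-fold cross-validation with in-fold undersampling.

    Undersampling of the majority class happens inside each training split
    only; every island appears in exactly one test fold at its natural class
    distribution. ``r`` defaults to the methylated fraction of the training
    split of each fold. Returns per-fold metrics plus pooled out-of-fold
    metrics.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(dataset) < k:
        raise ValueError("dataset smaller than the number of folds")
    y = dataset["y"].to_numpy()
    min_class = np.bincount(y, minlength=2).min()
    if min_class >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(dataset, y)
    else:
        logger.warning("a class has fewer than k members; falling back to "
                       "unstratified folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(dataset)

    fold_metrics: List[Dict] = []
    oof = dataset[["island_id"]].copy()
    oof["posterior"] = np.nan
    oof["label"] = -1
    for fold, (train_idx, test_idx) in enumerate(splits):
        train = dataset.iloc[train_idx]
        test = dataset.iloc[test_idx]
        balanced = balance_by_undersampling(train, seed=seed + fold)
        model = train_forest(balanced, seed=seed + fold, hyperparams=hyperparams)
        preds = predict_posteriors(model, test)
        r_fold = r if r is not None else float(train["y"].mean())
        hard = apply_top_r(preds, r_fold)
        oof.iloc[test_idx, oof.columns.get_loc("posterior")] = preds["posterior"].to_numpy()
        oof.iloc[test_idx, oof.columns.get_loc("label")] = hard["label"].to_numpy()
        if len(np.unique(test["y"])) == 2:
            fold_metrics.append(
                evaluate(test["y"], preds["posterior"], hard["label"]))
        else:
            fold_metrics.append({"note": "single-class test fold; metrics skipped"})
    pooled = evaluate(dataset["y"], oof["posterior"], oof["label"])
    return {"folds": fold_metrics, "pooled": pooled, "out_of_fold": oof}


def feature_importance(model: ModelBundle) -> pd.Series:
    """Mean-decrease-in-impurity importances in canonical feature order;
    non-negative and summing to 1."""
    imp = model.forest.feature_importances_
    return pd.Series(imp, index=list(model.feature_names), name="mdi_importance")
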