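"""Iteratively reweighted random forests (iRF) and model evaluation.

An iRF starts from uniform feature weights 1/p and repeats (default four
iterations): grow a forest whose trees each see a bootstrap sample of the
rows and a feature subspace sampled *with probability proportional to the
current weights*; measure each feature's Gini importance (total impurity
decrease); renormalize importances into the next iteration's weights.
Stable, predictive features accumulate weight across iterations while
noise features are starved.  The final model is the last iteration's
forest.  Regression uses variance-reduction splits and reports held-out
R²; classification uses Gini splits and reports AUROC (trapezoidal) and
AUPRC (step-wise precision-recall integral).
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    r2_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

DEFAULT_ITERATIONS = 4
DEFAULT_N_TREES = 500


def split_train_test(
    elements: Sequence[str], fraction: float = 0.5, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Reproducible random train/test partition of element ids."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ids = list(elements)
    if len(ids) < 2:
        raise ValueError("need at least 2 elements to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


@dataclass
class IRFIteration:
    """One reweighting step: the weights used, the forest, its importances."""

    weights: np.ndarray           # feature-sampling weights entering this iteration
    trees: list                   # (fitted tree, feature index array) pairs
    importances: np.ndarray       # normalized Gini importances measured on this forest


@dataclass
class IRFModel:
    """A fitted iteratively reweighted random forest."""

    task: str
    feature_names: list[str]
    iterations: list[IRFIteration]
    config: dict
    classes_: np.ndarray | None = None

    @property
    def final_weights(self) -> np.ndarray:
        return self.iterations[-1].importances

    @property
    def weight_history(self) -> pd.DataFrame:
        """Feature weights entering each iteration plus the final importances."""
        data = {f"iter{i + 1}": it.weights for i, it in enumerate(self.iterations)}
        data["final"] = self.final_weights
        return pd.DataFrame(data, index=self.feature_names)

    def _predict_trees(self, X: np.ndarray) -> np.ndarray:
        preds = []
        for tree, feats in self.iterations[-1].trees:
            if self.task == "regression":
                preds.append(tree.predict(X[:, feats]))
            else:
                proba = tree.predict_proba(X[:, feats])
                # map the tree's local classes onto the global positive class
                p_pos = np.zeros(len(X))
                for j, cls in enumerate(tree.classes_):
                    if cls == self.classes_[1]:
                        p_pos = proba[:, j]
                preds.append(p_pos)
        return np.mean(preds, axis=0)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predicted response (regression) or positive-class score (classification)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        return self._predict_trees(np.asarray(X, dtype=float))

    def save(self, path: str | Path) -> None:
        """Serialize to a bundle: JSON sidecar (config + weights) + pickle."""
        path = Path(path)
        bundle = {
            "task": self.task,
            "features": self.feature_names,
            "config": self.config,
            "weights_per_iteration": [it.weights.tolist() for it in self.iterations],
            "final_importances": self.final_weights.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(bundle, indent=2))
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "IRFModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _weighted_feature_subset(
    rng: np.random.Generator, weights: np.ndarray, mtry: int
) -> np.ndarray:
    p = len(weights)
    probs = weights + 1e-12
    probs = probs / probs.sum()
    return rng.choice(p, size=min(mtry, p), replace=False, p=probs)


def irf_fit(
    X: pd.DataFrame,
    y: Sequence[float],
    task: str = "regression",
    iterations: int = DEFAULT_ITERATIONS,
    n_trees: int = DEFAULT_N_TREES,
    mtry: int | None = None,
    seed: int = 0,
    min_samples_leaf: int = 1,
) -> IRFModel:
    """Fit an iRF to a feature matrix.

    Iteration 1 samples each tree's feature subspace uniformly (weights
    1/p); each later iteration samples features with probability
    proportional to the previous forest's normalized Gini importances.
    ``mtry`` defaults to ceil(sqrt(p)) for classification and max(1, p/3)
    for regression.  All randomness flows from ``seed``.
    """
    if task not in ("regression", "classification"):
        raise ValueError(f"unknown task {task!r}")
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(X.shape[1])]
    Xa = X[feature_names].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    ya = np.asarray(y)
    if np.isnan(Xa).any():
        raise ValueError("feature matrix contains missing values")
    n, p = Xa.shape
    classes = None
    if task == "regression":
        ya = ya.astype(float)
        if np.all(ya == ya[0]):
            raise ValueError("constant response")
    else:
        classes = np.unique(ya)
        if len(classes) != 2:
            raise ValueError(f"classification requires a binary response, got classes {classes}")
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p))) if task == "classification" else max(1, p // 3)

    rng = np.random.default_rng(seed)
    weights = np.full(p, 1.0 / p)
    its: list[IRFIteration] = []
    for _ in range(iterations):
        raw_importance = np.zeros(p)
        trees = []
        for _t in range(n_trees):
            rows = rng.integers(0, n, size=n)
            feats = _weighted_feature_subset(rng, weights, mtry)
            tree_seed = int(rng.integers(0, 2**31 - 1))
            if task == "regression":
                tree = DecisionTreeRegressor(random_state=tree_seed, min_samples_leaf=min_samples_leaf)
            else:
                tree = DecisionTreeClassifier(random_state=tree_seed, min_samples_leaf=min_samples_leaf)
            tree.fit(Xa[np.ix_(rows, feats)], ya[rows])
            raw_importance[feats] += tree.tree_.compute_feature_importances(normalize=False)
            trees.append((tree, feats))
        total = raw_importance.sum()
        importances = (
            raw_importance / total if total > 0 else np.full(p, 1.0 / p)
        )
        its.append(IRFIteration(weights.copy(), trees, importances))
        weights = importances
    config = {
        "iterations": iterations, "n_trees": n_trees, "mtry": mtry,
        "seed": seed, "min_samples_leaf": min_samples_leaf,
    }
    return IRFModel(task, feature_names, its, config, classes)


def evaluate_model(
    model: IRFModel, X_test: pd.DataFrame, y_test: Sequence[float]
) -> dict:
    """Held-out metrics: R² (regression) or AUROC/AUPRC plus curves."""
    y = np.asarray(y_test)
    scores = model.predict(X_test)
    if model.task == "regression":
        return {"r2": float(r2_score(y, scores)), "predictions": scores}
    if len(np.unique(y)) < 2:
        return {"auroc": float("nan"), "auprc": float("nan"),
                "flag": "single-class test set: AUROC undefined", "predictions": scores}
    y_bin = (y == model.classes_[1]).astype(int)
    fpr, tpr, _ = roc_curve(y_bin, scores)
    precision, recall, _ = precision_recall_curve(y_bin, scores)
    return {
        "auroc": float(roc_auc_score(y_bin, scores)),
        "auprc": float(average_precision_score(y_bin, scores)),
        "roc_curve": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        "pr_curve": pd.DataFrame({"recall": recall, "precision": precision}),
        "predictions": scores,
    }


def active_labels(expression: pd.Series, quantile: float = 0.75) -> pd.Series:
    """Binary active/inactive labels: active iff expression >= the given
    quantile (linear-interpolation quantile of the supplied values)."""
    cutoff = expression.quantile(quantile)
    return (expression >= cutoff).astype(int)
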