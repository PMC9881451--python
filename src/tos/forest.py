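"""Random-forest germline/somatic classification harness.

The modelling surface follows the model/results convention:
:class:`SomaticClassifier` is built from a labeled feature table and its
:meth:`~SomaticClassifier.fit` returns a
:class:`SomaticClassifierResults` carrying the fitted forest, ranked
feature importances, and evaluation/summary methods.  The protocol
around the forest — 1:1 class balancing, stratified 75/25 splitting,
grid search with deterministic tie-breaking, confusion-matrix
evaluation — lives here and is shared by the small-variant and SV
pipelines.

Hyperparameters use the classic forest vocabulary: ``features_per_split``
(mtry), ``num_trees`` (ntree) and ``min_node_size`` (nodesize).  The
small-variant optimum is (8, 1000, 5); the SV models use the default
(4, 400, 1).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "RFHyperparams",
    "SplitConfig",
    "EvaluationReport",
    "SomaticClassifier",
    "SomaticClassifierResults",
    "balance_one_to_one",
    "split_train_test",
    "grid_search_rf",
    "default_grid",
    "SNV_OPTIMUM",
    "SV_DEFAULT",
]

LABEL_COLUMN = "label"
POSITIVE = "somatic"
NEGATIVE = "germline"


@dataclass(frozen=True)
class RFHyperparams:
    features_per_split: int = 8
    num_trees: int = 1000
    min_node_size: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("features_per_split", "num_trees", "min_node_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def to_sklearn(self, n_features: int) -> RandomForestClassifier:
        if self.features_per_split > n_features:
            raise ValueError(
                f"features_per_split={self.features_per_split} exceeds "
                f"{n_features} available features"
            )
        return RandomForestClassifier(
            n_estimators=self.num_trees,
            max_features=self.features_per_split,
            min_samples_leaf=self.min_node_size,
            random_state=self.seed,
            n_jobs=1,
        )


SNV_OPTIMUM = RFHyperparams(features_per_split=8, num_trees=1000, min_node_size=5)
SV_DEFAULT = RFHyperparams(features_per_split=4, num_trees=400, min_node_size=1)


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "precision": self.precision, "recall": self.recall,
                "accuracy": self.accuracy,
            }
        )


def _require_label(df: pd.DataFrame) -> None:
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"feature table lacks a {LABEL_COLUMN!r} column")


def balance_one_to_one(df: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Down-sample the majority class, uniformly without replacement, to
    the minority-class count (1:1 somatic:germline)."""
    _require_label(df)
    counts = df[LABEL_COLUMN].value_counts()
    for cls in (POSITIVE, NEGATIVE):
        if counts.get(cls, 0) == 0:
            raise ValueError(f"class {cls!r} absent; cannot balance")
    n = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls in (POSITIVE, NEGATIVE):  # fixed order for determinism
        sub = df[df[LABEL_COLUMN] == cls]
        if len(sub) > n:
            keep = rng.choice(len(sub), size=n, replace=False)
            sub = sub.iloc[np.sort(keep)]
        parts.append(sub)
    return pd.concat(parts).sort_index()


def split_train_test(df: pd.DataFrame, cfg: SplitConfig = SplitConfig()):
    """Label-stratified train/test split (default 75/25); per-stratum
    train size matches round(train_fraction * n) within +/-1."""
    _require_label(df)
    if len(df) < 4:
        raise ValueError("need at least 4 records to split")
    counts = df[LABEL_COLUMN].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"stratum with fewer than 2 records: {small}")
    train, test = train_test_split(
        df,
        train_size=cfg.train_fraction,
        stratify=df[LABEL_COLUMN],
        random_state=cfg.seed,
        shuffle=True,
    )
    return train.sort_index(), test.sort_index()


def default_grid(n_features: int, seed: int = 0) -> list[RFHyperparams]:
    """Grid spanning both published optima: mtry in {2,4,8}, ntree in
    {400,1000}, nodesize in {1,5}."""
    return [
        RFHyperparams(m, t, s, seed=seed)
        for m in (2, 4, 8)
        if m <= n_features
        for t in (400, 1000)
        for s in (1, 5)
    ]


def grid_search_rf(
    train: pd.DataFrame,
    grid: Iterable[RFHyperparams] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> tuple[RFHyperparams, pd.DataFrame]:
    """Pick the grid point maximizing mean cross-validated accuracy.

    Ties break deterministically toward the cheaper model: fewer trees,
    then larger min_node_size, then smaller features_per_split.  Returns
    the winner and the full CV table.
    """
    _require_label(train)
    feats = list(feature_names) if feature_names else [c for c in train.columns if c != LABEL_COLUMN]
    grid = list(grid) if grid is not None else default_grid(len(feats), seed=seed)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = train[feats].to_numpy(dtype=float)
    y = (train[LABEL_COLUMN] == POSITIVE).to_numpy(dtype=int)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for _, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("cross-validation fold contains a single class")
    rows = []
    for hp in grid:
        accs = []
        for tr, te in folds:
            clf = replace(hp, seed=seed).to_sklearn(len(feats))
            clf.fit(X[tr], y[tr])
            accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        rows.append(
            {
                "features_per_split": hp.features_per_split,
                "num_trees": hp.num_trees,
                "min_node_size": hp.min_node_size,
                "cv_accuracy": float(np.mean(accs)),
            }
        )
    table = pd.DataFrame(rows)
    best_idx = min(
        range(len(grid)),
        key=lambda i: (
            -table.loc[i, "cv_accuracy"],
            grid[i].num_trees,
            -grid[i].min_node_size,
            grid[i].features_per_split,
        ),
    )
    return replace(grid[best_idx], seed=seed), table


class SomaticClassifier:
    """Random-forest somatic-vs-germline model over a labeled feature
    table (one row per variant, a ``label`` column plus numeric feature
    columns, sentinels at -1 for missing annotations)."""

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Sequence[str] | None = None,
        feature_names: Sequence[str] | None = None,
    ):
        if labels is None:
            _require_label(features)
            labels = features[LABEL_COLUMN]
            features = features.drop(columns=[LABEL_COLUMN])
        if feature_names is not None:
            features = features[list(feature_names)]
        self.feature_names = list(features.columns)
        self.X = features.to_numpy(dtype=float)
        self.y = np.asarray([1 if l == POSITIVE else 0 for l in labels], dtype=int)
        if len(self.X) == 0:
            raise ValueError("empty training set")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite feature values; impute sentinels first")

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame, feature_names=None):
        return cls(table, feature_names=feature_names)

    def fit(self, hp: RFHyperparams = SNV_OPTIMUM) -> "SomaticClassifierResults":
        clf = hp.to_sklearn(len(self.feature_names))
        clf.fit(self.X, self.y)
        return SomaticClassifierResults(clf, hp, self.feature_names, n_train=len(self.X))


class SomaticClassifierResults:
    """Fitted forest with ranked importances and evaluation helpers."""

    def __init__(self, model, hp, feature_names, n_train: int):
        self.model = model
        self.hyperparams = hp
        self.feature_names = list(feature_names)
        self.n_train = n_train

    @property
    def feature_importances(self) -> pd.Series:
        """Impurity-based importances, descending (nonnegative, sum 1)."""
        imp = pd.Series(self.model.feature_importances_, index=self.feature_names)
        return imp.sort_values(ascending=False)

    def top_features(self, k: int) -> list[str]:
        return self.feature_importances.index[:k].tolist()

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        return features[self.feature_names].to_numpy(dtype=float)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """P(somatic) per row."""
        proba = self.model.predict_proba(self._matrix(features))
        pos = list(self.model.classes_).index(1)
        return proba[:, pos]

    def classify(self, features: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return np.where(self.predict_proba(features) >= threshold, POSITIVE, NEGATIVE)

    def evaluate(self, test: pd.DataFrame, threshold: float = 0.5) -> EvaluationReport:
        """Confusion-matrix metrics on a labeled table; somatic is the
        positive class, called at the probability threshold."""
        _require_label(test)
        if len(test) == 0:
            raise ValueError("empty test set")
        pred = self.classify(test, threshold=threshold)
        truth = test[LABEL_COLUMN].to_numpy()
        tp = int(((pred == POSITIVE) & (truth == POSITIVE)).sum())
        fp = int(((pred == POSITIVE) & (truth == NEGATIVE)).sum())
        fn = int(((pred == NEGATIVE) & (truth == POSITIVE)).sum())
        tn = int(((pred == NEGATIVE) & (truth == NEGATIVE)).sum())
        return EvaluationReport(tp=tp, fp=fp, fn=fn, tn=tn)

    def summary(self, test: pd.DataFrame | None = None) -> str:
        hp = self.hyperparams
        lines = [
            "Somatic variant random-forest results",
            "=" * 42,
            f"trees {hp.num_trees}  mtry {hp.features_per_split}  "
            f"min node {hp.min_node_size}  seed {hp.seed}",
            f"training rows: {self.n_train}   features: {len(self.feature_names)}",
            "",
            "Top feature importances:",
        ]
        for name, val in self.feature_importances.head(10).items():
            lines.append(f"  {name:<24s} {val:.4f}")
        if test is not None:
            rep = self.evaluate(test)
            lines += [
                "",
                f"held-out n={rep.total}: precision {rep.precision:.4f}  "
                f"recall {rep.recall:.4f}  accuracy {rep.accuracy:.4f}",
            ]
        return "\n".join(lines)

    def plot_importances(self, k: int = 10, ax=None):
        import matplotlib.pyplot as plt

        imp = self.feature_importances.head(k)[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.4 * k + 1))
        ax.barh(imp.index, imp.values)
        ax.set_xlabel("importance")
        return ax

    # -- persistence ------------------------------------------------------

    def save(self, path, training_table: pd.DataFrame | None = None) -> None:
        """Serialize model + manifest (feature names, hyperparameters,
        seed, and a hash of the training table when provided)."""
        payload = {
            "model": self.model,
            "feature_names": self.feature_names,
            "hyperparams": {
                "features_per_split": self.hyperparams.features_per_split,
                "num_trees": self.hyperparams.num_trees,
                "min_node_size": self.hyperparams.min_node_size,
                "seed": self.hyperparams.seed,
            },
            "n_train": self.n_train,
        }
        if training_table is not None:
            h = hashlib.sha256(
                pd.util.hash_pandas_object(training_table, index=False).to_numpy().tobytes()
            ).hexdigest()
            payload["training_hash"] = h
        joblib.dump(payload, path)
        manifest = {k: v for k, v in payload.items() if k != "model"}
        with open(str(path) + ".manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SomaticClassifierResults":
        payload = joblib.load(path)
        hp = RFHyperparams(**payload["hyperparams"])
        return cls(payload["model"], hp, payload["feature_names"], payload["n_train"])
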