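"""Cross-species validation of profile-based homology prediction.

Trains MLP and random-forest classifiers to predict membership in a
curated gene set from NPP rows, after outlier nulling (3-sigma rule),
missingness filtering, row-wise linear interpolation and Cluster-Centroids
undersampling of the majority class.  Clade-level feature importance of a
fitted forest summarizes which branches of the species tree carry the
predictive evolutionary signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neural_network import MLPClassifier

from .cladepp import CladeMap

__all__ = [
    "MLDataset",
    "ClassifierSpec",
    "EvalMetrics",
    "clean",
    "cluster_centroids_undersample",
    "stratified_split",
    "train_and_eval",
    "clade_feature_importance",
    "CrossSpeciesValidation",
    "ValidationResults",
]

log = logging.getLogger(__name__)


@dataclass
class MLDataset:
    """Feature table (genes x species) with optional binary labels."""

    X: pd.DataFrame
    y: pd.Series | None = None

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.X.columns)

    def with_labels(self, positives: Iterable[str]) -> "MLDataset":
        positives = set(positives)
        y = pd.Series([int(g in positives) for g in self.X.index],
                      index=self.X.index, name="label")
        return MLDataset(self.X, y)


def clean(
    matrix: pd.DataFrame,
    max_missing_fraction: float = 0.20,
    sigma: float = 3.0,
) -> MLDataset:
    """Outlier-null, drop, and interpolate a feature matrix.

    Per feature, values strictly outside mean +/- ``sigma`` sample
    standard deviations become missing; then features, then samples, with
    strictly more than ``max_missing_fraction`` missing are dropped;
    remaining gaps are filled by linear interpolation along each gene row
    over the fixed feature order, with leading/trailing gaps taking the
    nearest observed value.  Idempotent on its own output.
    """
    X = matrix.astype(float).copy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        outlier = (X.sub(mu, axis=1).abs()).gt(sigma * sd, axis=1)
    X = X.mask(outlier)

    feat_missing = X.isna().mean(axis=0)
    X = X.loc[:, feat_missing <= max_missing_fraction]
    if X.shape[1] == 0:
        raise ValueError("all features dropped by the missingness filter")
    row_missing = X.isna().mean(axis=1)
    X = X.loc[row_missing <= max_missing_fraction]

    arr = X.to_numpy()
    positions = np.arange(arr.shape[1])
    for i in range(arr.shape[0]):
        row = arr[i]
        ok = ~np.isnan(row)
        if ok.all():
            continue
        if not ok.any():
            continue  # unreachable under the row filter unless all-missing allowed
        arr[i] = np.interp(positions, positions[ok], row[ok])
    return MLDataset(pd.DataFrame(arr, index=X.index, columns=X.columns))


def common_features(matrices: Sequence[pd.DataFrame]) -> list[str]:
    """Feature ids shared by every matrix, in the first matrix's order."""
    shared = set(matrices[0].columns)
    for m in matrices[1:]:
        shared &= set(m.columns)
    return [c for c in matrices[0].columns if c in shared]


def cluster_centroids_undersample(dataset: MLDataset, seed: int = 0) -> MLDataset:
    """Balance classes by replacing majority rows with K-means centroids.

    K-means with k = minority-class count is run on the majority rows
    (k-means++ init, Lloyd iterations, tol 1e-6, 300 iterations max); the
    majority class is replaced by the k centroids while minority rows pass
    through unchanged, so the output classes are equal in size.  When the
    minority is not smaller the dataset is returned unchanged.
    """
    if dataset.y is None:
        raise ValueError("undersampling needs labels")
    counts = dataset.y.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present")
    minority = counts.idxmin()
    majority = counts.idxmax()
    if counts[minority] >= counts[majority]:
        log.info("classes already balanced; undersampling is a no-op")
        return dataset

    k = int(counts[minority])
    maj_rows = dataset.X.loc[dataset.y == majority]
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-6,
                max_iter=300, random_state=seed)
    km.fit(maj_rows.to_numpy())
    centroids = pd.DataFrame(
        km.cluster_centers_, columns=dataset.X.columns,
        index=[f"centroid_{i:04d}" for i in range(k)],
    )
    min_rows = dataset.X.loc[dataset.y == minority]
    X = pd.concat([min_rows, centroids])
    y = pd.Series([minority] * len(min_rows) + [majority] * k, index=X.index,
                  name=dataset.y.name)
    return MLDataset(X, y)


@dataclass
class ClassifierSpec:
    """Hyperparameters of the two validated classifier families.

    MLP: three hidden layers (180, 90, 40), ReLU, Adam with initial
    learning rate 1e-4 and L2 coefficient 0.1.  RF: 55 trees, depth 15.
    """

    kind: str = "rf"  # "mlp" or "rf"
    hidden_layers: tuple[int, ...] = (180, 90, 40)
    learning_rate: float = 1e-4
    alpha: float = 0.1
    n_estimators: int = 55
    max_depth: int = 15
    max_iter: int = 500
    seed: int = 0

    def build(self):
        if self.kind == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=self.hidden_layers,
                activation="relu",
                solver="adam",
                learning_rate_init=self.learning_rate,
                alpha=self.alpha,
                max_iter=self.max_iter,
                random_state=self.seed,
            )
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=self.seed,
            )
        raise ValueError(f"unknown classifier kind: {self.kind!r}")


@dataclass
class EvalMetrics:
    """Binary-classification metrics with their confusion counts."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_confusion(cls, tp: int, fp: int, fn: int, tn: int) -> "EvalMetrics":
        total = tp + fp + fn + tn
        accuracy = (tp + tn) / total if total else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        return cls(accuracy, precision, recall, f1, tp, fp, fn, tn)

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "EvalMetrics":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        return cls.from_confusion(tp, fp, fn, tn)

    def asdict(self) -> dict:
        return asdict(self)


def stratified_split(
    dataset: MLDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[MLDataset, MLDataset]:
    """Stratified train/test split preserving class proportions."""
    if dataset.y is None:
        raise ValueError("splitting needs labels")
    X_tr, X_te, y_tr, y_te = train_test_split(
        dataset.X, dataset.y, test_size=test_fraction,
        stratify=dataset.y, random_state=seed,
    )
    return MLDataset(X_tr, y_tr), MLDataset(X_te, y_te)


def train_and_eval(
    train: MLDataset,
    test: MLDataset,
    spec: ClassifierSpec,
    param_grid: Mapping[str, Sequence] | None = None,
    cv: int = 5,
) -> tuple[EvalMetrics, object]:
    """Fit the specified classifier and evaluate on the held-out set.

    With ``param_grid`` the hyperparameters are grid-searched by
    ``cv``-fold cross-validation on the training set and the best
    configuration refitted.  Returns the metrics and the fitted model.
    """
    if train.y is None or test.y is None:
        raise ValueError("train and test must carry labels")
    if train.y.nunique() < 2:
        raise ValueError("training labels contain a single class")
    if list(train.X.columns) != list(test.X.columns):
        raise ValueError("train and test feature ids differ")
    model = spec.build()
    if param_grid:
        model = GridSearchCV(model, dict(param_grid), cv=cv, scoring="f1")
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(train.X.to_numpy(), train.y.to_numpy())
    pred = model.predict(test.X.to_numpy())
    metrics = EvalMetrics.from_predictions(test.y.to_numpy(), pred)
    if param_grid:
        model = model.best_estimator_
    return metrics, model


def clade_feature_importance(
    model,
    feature_ids: Sequence[str],
    clade_map: CladeMap | Mapping[str, str],
    min_species: int | None = None,
) -> pd.DataFrame:
    """Impurity importances of a fitted forest averaged within clades.

    Returns a table (clade, mean_importance, se, n_species) with standard
    error sd/sqrt(n) (0 for single-species clades); clades with fewer than
    ``min_species`` surviving features are omitted with a warning.
    """
    importances = pd.Series(model.feature_importances_, index=list(feature_ids))
    if not isinstance(clade_map, CladeMap):
        clade_map = CladeMap(clade_map, min_species=min_species or 1)
    if min_species is None:
        min_species = clade_map.min_species
    rows = []
    for clade in clade_map.clades:
        members = [s for s in clade_map.species_of(clade) if s in importances.index]
        if not members:
            warnings.warn(f"clade {clade!r} has no surviving features; omitted",
                          stacklevel=2)
            continue
        if len(members) < min_species:
            continue
        vals = importances[members]
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append((clade, float(vals.mean()), se, len(vals)))
    return pd.DataFrame(rows, columns=["clade", "mean_importance", "se", "n_species"]
                        ).set_index("clade")


class CrossSpeciesValidation:
    """End-to-end validation study over one or more NPP matrices.

    Cleans each matrix, restricts to the shared species, stacks them,
    attaches binary labels (membership in the positive gene set), splits
    stratified 80/20, balances the training partition by
    Cluster-Centroids undersampling, and fits the requested classifiers.
    """

    def __init__(
        self,
        matrices: Sequence[pd.DataFrame],
        positives: Iterable[str],
        clade_map: CladeMap | Mapping[str, str] | None = None,
        test_fraction: float = 0.2,
        max_missing_fraction: float = 0.20,
        sigma: float = 3.0,
        seed: int = 0,
    ):
        self.matrices = list(matrices)
        self.positives = set(positives)
        self.clade_map = clade_map
        self.test_fraction = test_fraction
        self.max_missing_fraction = max_missing_fraction
        self.sigma = sigma
        self.seed = seed

    def fit(self, kinds: Sequence[str] = ("mlp", "rf")) -> "ValidationResults":
        cleaned = [clean(m, self.max_missing_fraction, self.sigma).X
                   for m in self.matrices]
        shared = common_features(cleaned)
        if not shared:
            raise ValueError("no species columns shared across matrices")
        stacked = pd.concat([c[shared] for c in cleaned])
        dataset = MLDataset(stacked).with_labels(self.positives)
        train, test = stratified_split(dataset, self.test_fraction, self.seed)
        balanced = cluster_centroids_undersample(train, self.seed)
        metrics: dict[str, EvalMetrics] = {}
        models: dict[str, object] = {}
        for kind in kinds:
            spec = ClassifierSpec(kind=kind, seed=self.seed)
            metrics[kind], models[kind] = train_and_eval(balanced, test, spec)
        return ValidationResults(self, metrics, models, train, test)


@dataclass
class ValidationResults:
    """Fitted validation study: per-model metrics and handles."""

    study: CrossSpeciesValidation
    metrics: dict[str, EvalMetrics]
    models: dict[str, object]
    train: MLDataset
    test: MLDataset

    def clade_importance(self) -> pd.DataFrame:
        if "rf" not in self.models:
            raise ValueError("clade importance needs a fitted random forest")
        if self.study.clade_map is None:
            raise ValueError("no clade map supplied to the study")
        return clade_feature_importance(
            self.models["rf"], self.test.feature_ids, self.study.clade_map
        )

    def summary(self) -> str:
        lines = ["Cross-species validation", "========================",
                 f"train samples: {self.train.n_samples} (balanced)",
                 f"test samples:  {self.test.n_samples}", ""]
        for kind, m in self.metrics.items():
            lines.append(
                f"{kind.upper():4s} accuracy={m.accuracy:.4f} precision={m.precision:.4f}"
                f" recall={m.recall:.4f} f1={m.f1:.4f}"
                f"  (TP={m.tp} FP={m.fp} FN={m.fn} TN={m.tn})"
            )
        return "\n".join(lines)
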