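"""Binary healthy-vs-pathologic classification of radiomic feature tables.

The training protocol mirrors the study design for imbalanced cohorts:

* features are ranked per fold with minimum-redundancy-maximum-relevance
  (mRMR) on quantile-discretized mutual information and the top ``d``
  (default 9) are retained — the d ≈ √n heuristic is surfaced as a
  warning when violated, not enforced;
* Monte-Carlo (MC) cross-validation folds draw a class-balanced
  validation set sized by 20% of the minority (healthy) group, with
  pairwise-distinct validation sets across folds;
* the training split is balanced by SMOTE oversampling of the healthy
  minority;
* a heterogeneous ensemble (regularized logistic regression, random
  forest, k-nearest-neighbors, RBF-kernel SVM by default) is fitted per
  fold; at test time every classifier from every fold votes, and each
  plane receives the mean pathologic probability ρ across all
  classifiers.

Feature selection and SMOTE only ever see training rows.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .tissue import BINARY_NEGATIVE, BINARY_POSITIVE

META_COLUMNS = ("plane_id", "roi_id", "tissue_class", "binary_label")


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """The feature block of a FeatureTable (all non-metadata columns)."""
    cols = [c for c in table.columns if c not in META_COLUMNS]
    return table[cols]


def binary_target(table: pd.DataFrame) -> np.ndarray:
    """0 = healthy, 1 = pathologic."""
    return (table["binary_label"].to_numpy() == BINARY_POSITIVE).astype(int)


# ------------------------------------------------------------------ mRMR

def _quantile_discretize(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Quantile-bin a feature column into integer codes."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (nats) between two small-alphabet integer codes."""
    ja = np.unique(a, return_inverse=True)[1]
    jb = np.unique(b, return_inverse=True)[1]
    joint = np.zeros((ja.max() + 1, jb.max() + 1))
    np.add.at(joint, (ja, jb), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank(X: pd.DataFrame, y: np.ndarray,
              n_select: int | None = None, n_bins: int = 4) -> list[str]:
    """Greedy mRMR feature ranking.

    The first feature maximizes relevance (MI with the label after
    4-quantile discretization); each subsequent pick maximizes
    relevance − mean MI with the already-selected features. Ties break
    by column order, making the ranking fully deterministic.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least two classes")
    cols = list(X.columns)
    n_select = n_select or len(cols)
    disc = {c: _quantile_discretize(X[c].to_numpy(dtype=float), n_bins)
            for c in cols}
    relevance = {c: _mutual_information(disc[c], y) for c in cols}
    selected: list[str] = []
    redundancy_sum = {c: 0.0 for c in cols}
    remaining = list(cols)
    while remaining and len(selected) < n_select:
        if selected:
            last = selected[-1]
            for c in remaining:
                redundancy_sum[c] += _mutual_information(disc[c], disc[last])
            k = len(selected)
            scores = [relevance[c] - redundancy_sum[c] / k for c in remaining]
        else:
            scores = [relevance[c] for c in remaining]
        best = int(np.argmax(scores))  # argmax keeps first on ties
        selected.append(remaining.pop(best))
    return selected


# ------------------------------------------------------------------ SMOTE

def smote_oversample(minority: np.ndarray, k_neighbors: int,
                     n_synthetic: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Synthetic minority oversampling.

    Each synthetic row is ``x + t (x_nn − x)`` with ``t ~ U(0, 1)`` and
    ``x_nn`` one of the ``k_neighbors`` nearest minority neighbors of a
    randomly chosen minority row ``x``.
    """
    minority = np.asarray(minority, dtype=float)
    n = minority.shape[0]
    if n < 2:
        raise ValueError("minority class must have at least 2 samples")
    if not 1 <= k_neighbors < n:
        raise ValueError("k_neighbors must be in [1, minority size)")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]))
    d2 = ((minority[:, None, :] - minority[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1)[:, :k_neighbors]
    base = rng.integers(0, n, n_synthetic)
    pick = rng.integers(0, k_neighbors, n_synthetic)
    t = rng.uniform(0.0, 1.0, n_synthetic)[:, None]
    x = minority[base]
    x_nn = minority[nn_idx[base, pick]]
    return x + t * (x_nn - x)


def balance_with_smote(X: np.ndarray, y: np.ndarray, k_neighbors: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by SMOTE-oversampling the minority class."""
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes required for balancing")
    minority_label = int(np.argmin(counts))
    n_synth = int(counts.max() - counts.min())
    if n_synth == 0:
        return X, y
    minority = X[y == minority_label]
    k = min(k_neighbors, len(minority) - 1)
    synth = smote_oversample(minority, k, n_synth, rng)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_synth, minority_label)])
    return X_out, y_out


# ------------------------------------------------------------------ folds

@dataclasses.dataclass(frozen=True)
class MCFold:
    """One Monte-Carlo train/validation split with a balanced validation set."""

    fold_id: int
    validation_ids: tuple[str, ...]
    training_ids: tuple[str, ...]
    seed: int


def build_mc_folds(table: pd.DataFrame, n_folds: int = 20,
                   validation_fraction: float = 0.2,
                   seed: int = 0) -> list[MCFold]:
    """Draw ``n_folds`` unique MC folds.

    The validation set holds ``v = round(fraction × minority size)`` planes
    of each binary class; all remaining planes train. No two folds share a
    validation set.
    """
    y = binary_target(table)
    ids = table["plane_id"].to_numpy()
    healthy_ids = ids[y == 0]
    path_ids = ids[y == 1]
    minority = min(len(healthy_ids), len(path_ids))
    if minority < 5:
        raise ValueError("minority class must have at least 5 planes")
    v = int(round(validation_fraction * minority))
    v = max(v, 1)
    ss = np.random.SeedSequence(seed)
    folds: list[MCFold] = []
    seen: set[frozenset] = set()
    attempts = 0
    while len(folds) < n_folds:
        attempts += 1
        if attempts > 100 * n_folds:
            raise ValueError("requested n_folds exceeds distinct-subset capacity")
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        val = np.concatenate([
            rng.choice(healthy_ids, v, replace=False),
            rng.choice(path_ids, v, replace=False),
        ])
        key = frozenset(val)
        if key in seen:
            continue
        seen.add(key)
        train = tuple(i for i in ids if i not in key)
        folds.append(MCFold(
            fold_id=len(folds),
            validation_ids=tuple(val),
            training_ids=train,
            seed=int(child.generate_state(1)[0] % (2**31)),
        ))
    return folds


# ------------------------------------------------------------------ metrics

@dataclasses.dataclass
class BinaryMetrics:
    """Confusion counts and derived rates; pathologic is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        tot = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / tot if tot else 0.0

    @property
    def sensitivity(self) -> float:
        den = self.tp + self.fn
        return self.tp / den if den else 0.0

    @property
    def specificity(self) -> float:
        den = self.tn + self.fp
        return self.tn / den if den else 0.0

    @classmethod
    def from_predictions(cls, y_pred: np.ndarray, y_true: np.ndarray) -> "BinaryMetrics":
        y_pred = np.asarray(y_pred).astype(int)
        y_true = np.asarray(y_true).astype(int)
        if y_pred.shape != y_true.shape:
            raise ValueError("prediction/truth length mismatch")
        return cls(tp=int(((y_pred == 1) & (y_true == 1)).sum()),
                   tn=int(((y_pred == 0) & (y_true == 0)).sum()),
                   fp=int(((y_pred == 1) & (y_true == 0)).sum()),
                   fn=int(((y_pred == 0) & (y_true == 1)).sum()))

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "tp": self.tp, "tn": self.tn,
                "fp": self.fp, "fn": self.fn}


def score(y_pred: np.ndarray, y_true: np.ndarray) -> BinaryMetrics:
    """Confusion counts + accuracy/sensitivity/specificity."""
    return BinaryMetrics.from_predictions(y_pred, y_true)


# ------------------------------------------------------------------ model

def _make_logistic(seed: int) -> Pipeline:
    return Pipeline([("scale", StandardScaler()),
                     ("clf", LogisticRegression(max_iter=2000,
                                                random_state=seed))])


def _make_forest(seed: int) -> Pipeline:
    return Pipeline([("clf", RandomForestClassifier(n_estimators=100,
                                                    random_state=seed))])


def _make_knn(seed: int) -> Pipeline:
    return Pipeline([("scale", StandardScaler()),
                     ("clf", KNeighborsClassifier(n_neighbors=5))])


def _make_svm(seed: int) -> Pipeline:
    return Pipeline([("scale", StandardScaler()),
                     ("clf", SVC(kernel="rbf", probability=True,
                                 random_state=seed))])


def default_roster() -> dict[str, Callable[[int], Pipeline]]:
    """Four distinct supervised families, each emitting P(pathologic)."""
    return {"logistic": _make_logistic, "random_forest": _make_forest,
            "knn": _make_knn, "svm_rbf": _make_svm}


@dataclasses.dataclass
class FoldFit:
    fold: MCFold
    selected_features: list[str]
    classifiers: dict[str, Pipeline]
    validation_metrics: dict[str, BinaryMetrics]


class ScarClassifier:
    """Healthy-vs-pathologic ensemble model over a radiomic FeatureTable.

    Parameters
    ----------
    table : DataFrame
        FeatureTable with metadata columns and one column per feature.
    d : int
        Number of top-ranked mRMR features kept per fold (default 9).
    n_folds : int
        Number of unique Monte-Carlo folds (default 20).
    validation_fraction : float
        Fraction of the minority class sizing the balanced validation set.
    roster : mapping name -> factory(seed) -> sklearn estimator
        Classifier families; defaults to four distinct families.
    smote_k : int
        SMOTE neighbor count.
    """

    def __init__(self, table: pd.DataFrame, d: int = 9, n_folds: int = 20,
                 validation_fraction: float = 0.2,
                 roster: Mapping[str, Callable[[int], Pipeline]] | None = None,
                 smote_k: int = 5):
        self.table = table.reset_index(drop=True)
        self.feature_names = list(feature_matrix(self.table).columns)
        if not 1 <= d <= len(self.feature_names):
            raise ValueError("d must be in [1, number of features]")
        n_train_est = len(self.table)
        guide = np.sqrt(n_train_est)
        if abs(d - guide) > 0.5 * guide:
            warnings.warn(
                f"selected feature count d={d} is far from the d≈√n guidance "
                f"(√{n_train_est} ≈ {guide:.1f})", stacklevel=2)
        self.d = d
        self.n_folds = n_folds
        self.validation_fraction = validation_fraction
        self.roster = dict(roster or default_roster())
        self.smote_k = smote_k

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame, **kwargs) -> "ScarClassifier":
        return cls(table, **kwargs)

    # -- fitting -----------------------------------------------------------

    def _fit_fold(self, fold: MCFold) -> FoldFit:
        tab = self.table.set_index("plane_id")
        train = tab.loc[list(fold.training_ids)]
        val = tab.loc[list(fold.validation_ids)]
        X_train = train[self.feature_names]
        y_train = (train["binary_label"].to_numpy() == BINARY_POSITIVE).astype(int)
        selected = mrmr_rank(X_train, y_train, n_select=self.d)
        rng = np.random.default_rng(fold.seed)
        Xb, yb = balance_with_smote(X_train[selected].to_numpy(dtype=float),
                                    y_train, self.smote_k, rng)
        classifiers: dict[str, Pipeline] = {}
        val_metrics: dict[str, BinaryMetrics] = {}
        X_val = val[selected].to_numpy(dtype=float)
        y_val = (val["binary_label"].to_numpy() == BINARY_POSITIVE).astype(int)
        for name, factory in self.roster.items():
            clf = factory(fold.seed)
            clf.fit(Xb, yb)
            classifiers[name] = clf
            val_metrics[name] = score(clf.predict(X_val), y_val)
        return FoldFit(fold=fold, selected_features=selected,
                       classifiers=classifiers,
                       validation_metrics=val_metrics)

    def fit(self, seed: int = 0) -> "ScarClassifierResults":
        """Fit the full MC-fold ensemble; returns a Results object."""
        folds = build_mc_folds(self.table, self.n_folds,
                               self.validation_fraction, seed)
        fits = [self._fit_fold(f) for f in folds]
        return ScarClassifierResults(model=self, fold_fits=fits, seed=seed)


class ScarClassifierResults:
    """Fitted MC-fold ensemble: per-fold fits, metrics, and prediction."""

    def __init__(self, model: ScarClassifier, fold_fits: Sequence[FoldFit],
                 seed: int):
        self.model = model
        self.fold_fits = list(fold_fits)
        self.seed = seed

    # -- validation-side reporting ----------------------------------------

    def validation_metrics_frame(self) -> pd.DataFrame:
        rows = []
        for ff in self.fold_fits:
            for clf_name, m in ff.validation_metrics.items():
                rows.append({"fold_id": ff.fold.fold_id, "classifier": clf_name,
                             **m.as_dict()})
        return pd.DataFrame(rows)

    def pooled_validation_metrics(self) -> BinaryMetrics:
        """Confusion counts pooled over folds and classifiers."""
        tp = tn = fp = fn = 0
        for ff in self.fold_fits:
            for m in ff.validation_metrics.values():
                tp, tn, fp, fn = tp + m.tp, tn + m.tn, fp + m.fp, fn + m.fn
        return BinaryMetrics(tp=tp, tn=tn, fp=fp, fn=fn)

    def selection_frequency(self) -> pd.Series:
        """How often each feature was among the top-d across folds."""
        counts: dict[str, int] = {}
        for ff in self.fold_fits:
            for name in ff.selected_features:
                counts[name] = counts.get(name, 0) + 1
        return pd.Series(counts).sort_values(ascending=False) / len(self.fold_fits)

    # -- test-side prediction ---------------------------------------------

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        """Per-plane votes and mean probability ρ on a FeatureTable.

        Every classifier of every fold contributes one pathologic
        probability; the binary vote is the classifier majority with
        ρ ≥ 0.5 breaking even splits toward pathologic.
        """
        missing = [c for c in self.model.feature_names if c not in table.columns]
        if missing:
            raise ValueError(f"feature columns missing from table: {missing[:5]}")
        probs = []
        for ff in self.fold_fits:
            X = table[ff.selected_features].to_numpy(dtype=float)
            for name, clf in ff.classifiers.items():
                pos = list(clf.classes_).index(1)
                probs.append(clf.predict_proba(X)[:, pos])
        P = np.asarray(probs)              # (n_classifiers_total, n_planes)
        rho = P.mean(axis=0)
        votes = (P >= 0.5).sum(axis=0)
        n_clf = P.shape[0]
        majority = votes * 2 > n_clf
        tie = votes * 2 == n_clf
        vote = np.where(tie, rho >= 0.5, majority).astype(int)
        out = pd.DataFrame({
            "plane_id": table["plane_id"].to_numpy(),
            "rho": rho,
            "vote": np.where(vote == 1, BINARY_POSITIVE, BINARY_NEGATIVE),
        })
        if "roi_id" in table:
            out["roi_id"] = table["roi_id"].to_numpy()
        if "tissue_class" in table:
            out["tissue_class"] = table["tissue_class"].to_numpy()
        return out

    def evaluate(self, table: pd.DataFrame) -> BinaryMetrics:
        """Score ensemble votes against a labelled FeatureTable."""
        pred = self.predict(table)
        y_true = binary_target(table)
        y_pred = (pred["vote"].to_numpy() == BINARY_POSITIVE).astype(int)
        return score(y_pred, y_true)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        vm = self.validation_metrics_frame()
        pooled = self.pooled_validation_metrics()
        top = self.selection_frequency().head(5)
        lines = [
            "Healthy-vs-pathologic radiomics ensemble (MC cross-validation)",
            "=" * 64,
            f"folds: {len(self.fold_fits)}   classifiers/fold: "
            f"{len(self.model.roster)}   features/fold (d): {self.model.d}",
            f"root seed: {self.seed}",
            "",
            "Pooled validation metrics (all folds x classifiers):",
            f"  accuracy    {pooled.accuracy:8.4f}",
            f"  sensitivity {pooled.sensitivity:8.4f}",
            f"  specificity {pooled.specificity:8.4f}",
            "",
            "Per-classifier mean ± sd validation accuracy:",
        ]
        for name, grp in vm.groupby("classifier"):
            lines.append(f"  {name:<16} {grp['accuracy'].mean():.4f} "
                         f"± {grp['accuracy'].std():.4f}")
        lines += ["", "Most frequently selected features (fraction of folds):"]
        for name, frac in top.items():
            lines.append(f"  {name:<48} {frac:.2f}")
        return "\n".join(lines)
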