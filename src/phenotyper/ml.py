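"""Cross-validated prediction of raceme branch counts and drought stress.

Two supervised tasks close the pipeline:

* **Branch-count regression** — raceme branch number is predicted from plant
  age (DAS), the number of flower pixels and the estimated flower count.
  Branch counts are many-valued and long-tailed, so this is treated as a
  regression whose "accuracy" is the fraction of predictions that match the
  true integer count after rounding (half-up).
* **Drought-stress classification** — a binary stressed/unstressed label on
  a single assessment day is predicted from a 20-feature table of growth,
  NIR, weight and phenology attributes, after down-sampling the majority
  class to balance.

Both run under k-fold cross validation (default k=5, shuffled, unstratified)
and report the per-fold metric plus its mean and standard deviation. ROC AUC
is computed from the rank statistic (Mann-Whitney; ties count half), not via
a library call.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import HuberRegressor, LinearRegression, LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

#: Branch-regression feature columns, in assembly order.
BRANCH_FEATURES = ("das", "flower_pixels", "est_flowers")

#: Stress-classification feature columns in the canonical reporting order.
#: flowering_group is ordinal: early=0, intermediate=1, late=2.
STRESS_FEATURES = (
    "nir_mean",
    "nir_p75",
    "pixels_tv",
    "d_pixels_tv",
    "hull_tv",
    "d_hull_tv",
    "pixels_sv",
    "d_pixels_sv",
    "hull_sv",
    "d_hull_sv",
    "weight_before",
    "weight_after",
    "area_below_rim",
    "height",
    "width",
    "d_height",
    "d_width",
    "exg",
    "flowering_group",
    "n_branches",
)

FLOWERING_GROUP_CODES = {"early": 0, "intermediate": 1, "late": 2}

REGRESSORS = {
    "linear": LinearRegression,
    "huber": lambda: HuberRegressor(max_iter=1000),
}


def _classifiers(seed: int) -> Dict[str, object]:
    return {
        "random_forest": RandomForestClassifier(random_state=seed),
        "lda": LinearDiscriminantAnalysis(),
        "logistic": LogisticRegression(max_iter=1000),
        "knn": KNeighborsClassifier(n_neighbors=1),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "svm": SVC(random_state=seed),
    }


CLASSIFIER_NAMES = ("random_forest", "lda", "logistic", "knn", "decision_tree", "svm")


@dataclasses.dataclass
class LabeledFeatureTable:
    """Feature matrix plus label and bookkeeping of dropped rows."""

    frame: pd.DataFrame  # feature columns + "label" (+ group keys if present)
    feature_columns: Tuple[str, ...]
    label_name: str
    n_dropped: int = 0

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_columns)].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclasses.dataclass
class CVReport:
    """Per-fold metric values with summary statistics."""

    algorithm: str
    metric: str
    per_fold: List[float]
    n_total: int
    n_train: int  # of the largest test fold's complement
    n_test: int  # largest test fold
    seed: int
    flagged: bool = False
    note: str = ""
    aux_per_fold: Optional[List[float]] = None  # e.g. accuracy when metric=ROC AUC
    aux_metric: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold)) if self.per_fold else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.per_fold, ddof=1)) if len(self.per_fold) > 1 else 0.0

    def to_dict(self) -> dict:
        d = {
            "algorithm": self.algorithm,
            "metric": self.metric,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
            "n_total": self.n_total,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
            "flagged": self.flagged,
            "note": self.note,
        }
        if self.aux_per_fold is not None:
            d["aux_metric"] = self.aux_metric
            d["aux_per_fold"] = self.aux_per_fold
            d["aux_mean"] = float(np.mean(self.aux_per_fold))
            d["aux_sd"] = (
                float(np.std(self.aux_per_fold, ddof=1))
                if len(self.aux_per_fold) > 1
                else 0.0
            )
        return d


def _finish_table(
    frame: pd.DataFrame, features: Sequence[str], label_col: str, label_name: str
) -> LabeledFeatureTable:
    cols = list(features) + [label_col]
    sub = frame[cols + [c for c in ("plant_id", "das") if c in frame.columns and c not in cols]]
    complete = sub.dropna(subset=cols)
    if complete.empty:
        raise ValueError("no labeled rows with complete features")
    out = complete.rename(columns={label_col: "label"}).reset_index(drop=True)
    return LabeledFeatureTable(
        frame=out,
        feature_columns=tuple(features),
        label_name=label_name,
        n_dropped=len(sub) - len(complete),
    )


def assemble_branch_features(
    flower_table: pd.DataFrame, drop: Sequence[str] = ()
) -> LabeledFeatureTable:
    """Branch-count table: (das, flower_pixels, est_flowers) -> branch_count.

    ``drop`` removes feature columns for ablation runs (e.g. flower_pixels,
    which is nearly collinear with est_flowers). Rows with any missing
    selected feature or label are dropped and counted.
    """
    features = [f for f in BRANCH_FEATURES if f not in set(drop)]
    if not features:
        raise ValueError("all features dropped")
    return _finish_table(flower_table, features, "branch_count", "branch_count")


def assemble_stress_features(
    trait_table: pd.DataFrame, das: int = 49
) -> LabeledFeatureTable:
    """Stress table on the assessment day (default 49 DAS), 20 features.

    Expects one row per plant with the :data:`STRESS_FEATURES` columns (the
    Δ columns are differences between the assessment day and the previous
    imaging day, i.e. 47 vs 49 DAS on an every-other-day schedule), a
    ``stress`` 0/1 label, and optionally a ``das`` column to select on.
    ``flowering_group`` may be given as strings and is encoded ordinally
    early=0, intermediate=1, late=2. Rows with missing features (e.g. an
    unpaired NIR day) are dropped and counted.
    """
    frame = trait_table
    if "das" in frame.columns:
        frame = frame[frame["das"] == das]
        if frame.empty:
            raise ValueError(f"no rows for assessment day das={das}")
    frame = frame.copy()
    if frame["flowering_group"].dtype == object:
        frame["flowering_group"] = frame["flowering_group"].map(
            lambda g: FLOWERING_GROUP_CODES.get(g, g) if isinstance(g, str) else g
        )
    return _finish_table(frame, STRESS_FEATURES, "stress", "stress")


def downsample_balance(table: LabeledFeatureTable, seed: int) -> LabeledFeatureTable:
    """Down-sample the majority class to the minority size, without replacement.

    Every minority row is preserved; the result has exactly twice the
    minority count and is deterministic for a given seed.
    """
    y = table.frame["label"]
    counts = y.value_counts()
    if len(counts) != 2 or (counts == 0).any():
        raise ValueError(f"need two non-empty classes, got {counts.to_dict()}")
    minority = counts.idxmin()
    majority = counts.idxmax()
    if counts[minority] == counts[majority]:
        return table
    rng = np.random.default_rng(seed)
    maj_idx = np.nonzero((y == majority).to_numpy())[0]
    keep_maj = rng.choice(maj_idx, size=int(counts[minority]), replace=False)
    keep = np.sort(np.concatenate([np.nonzero((y == minority).to_numpy())[0], keep_maj]))
    return LabeledFeatureTable(
        frame=table.frame.iloc[keep].reset_index(drop=True),
        feature_columns=table.feature_columns,
        label_name=table.label_name,
        n_dropped=table.n_dropped,
    )


def kfold_split(n: int, k: int = 5, seed: int = 0) -> List[np.ndarray]:
    """Shuffled k-fold test-index lists partitioning range(n), sizes within 1."""
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n))]


def round_half_up(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer, .5 away from zero upward (unlike bankers')."""
    return np.floor(np.asarray(values, float) + 0.5).astype(int)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney rank statistic; ties count 0.5.

    Probability that a random positive outscores a random negative.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def cv_regression(
    table: LabeledFeatureTable, algorithm: str = "linear", k: int = 5, seed: int = 0
) -> CVReport:
    """k-fold CV regression of integer counts; accuracy = rounded exact match.

    Besides the rounded-match accuracy, ``aux_per_fold`` carries
    ``1 - mean absolute percentage error`` per fold as an alternative,
    threshold-free view of regression quality.
    """
    if algorithm not in REGRESSORS:
        raise ValueError(f"unknown regressor {algorithm!r}; choose from {sorted(REGRESSORS)}")
    X, y = table.X, table.y.astype(float)
    flagged = bool(np.all(X.std(axis=0) == 0))
    folds = kfold_split(len(y), k=k, seed=seed)
    acc, inv_mape = [], []
    for test in folds:
        train = np.setdiff1d(np.arange(len(y)), test)
        model = REGRESSORS[algorithm]()
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        acc.append(float(np.mean(round_half_up(pred) == y[test].astype(int))))
        nonzero = y[test] != 0
        if nonzero.any():
            mape = float(np.mean(np.abs((pred[nonzero] - y[test][nonzero]) / y[test][nonzero])))
            inv_mape.append(1.0 - mape)
    sizes = [len(t) for t in folds]
    n_test = max(sizes)
    return CVReport(
        algorithm=algorithm,
        metric="rounded-match accuracy",
        per_fold=acc,
        n_total=len(y),
        n_train=len(y) - n_test,
        n_test=n_test,
        seed=seed,
        flagged=flagged,
        note="all features constant" if flagged else "",
        aux_per_fold=inv_mape,
        aux_metric="1 - MAPE",
    )


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def cv_classification(
    table: LabeledFeatureTable, algorithm: str = "random_forest", k: int = 5, seed: int = 0
) -> CVReport:
    """k-fold CV binary classification reporting ROC AUC (and accuracy).

    Scores are class-1 probabilities where the model provides them, else the
    decision function (AUC is invariant to monotone transforms, so the two
    are interchangeable). A test fold containing a single class has no
    defined AUC; it is skipped and the report flagged. KNN runs with K=1.
    """
    if algorithm not in CLASSIFIER_NAMES:
        raise ValueError(
            f"unknown classifier {algorithm!r}; choose from {CLASSIFIER_NAMES}"
        )
    X, y = table.X, table.y.astype(int)
    folds = kfold_split(len(y), k=k, seed=seed)
    aucs, accs = [], []
    skipped = 0
    for test in folds:
        train = np.setdiff1d(np.arange(len(y)), test)
        if len(np.unique(y[train])) < 2:
            skipped += 1  # nothing to learn from a single-class training set
            continue
        model = _classifiers(seed)[algorithm]
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        accs.append(float(np.mean(pred == y[test])))
        if len(np.unique(y[test])) < 2:
            skipped += 1
            continue
        aucs.append(rank_auc(_scores(model, X[test]), y[test]))
    sizes = [len(t) for t in folds]
    n_test = max(sizes)
    return CVReport(
        algorithm=algorithm,
        metric="ROC AUC",
        per_fold=aucs,
        n_total=len(y),
        n_train=len(y) - n_test,
        n_test=n_test,
        seed=seed,
        flagged=skipped > 0,
        note=f"{skipped} single-class fold(s) skipped for AUC" if skipped else "",
        aux_per_fold=accs,
        aux_metric="accuracy",
    )


def accuracy_from_counts(correct: int, total: int) -> float:
    """Percentage accuracy from counts, to two decimals (e.g. 170/175 -> 97.14)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    return round(100.0 * correct / total, 2)
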