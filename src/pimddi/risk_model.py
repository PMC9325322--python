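"""Bleeding-risk classification workflow.

The workflow mirrors a standard imbalanced-outcome learning protocol:
an 80/20 split stratified on the bleeding-ADE outcome, SMOTE class
rebalancing, 10-fold cross-validated hyperparameter tuning of three
classifier families (random forest, gradient-boosted trees, RBF support
vector machine) by mean ROC AUC, operating-point selection at the threshold
minimizing the Euclidean distance of (sensitivity, specificity) to the ideal
point (1, 1), and evaluation on the held-out test set.

SMOTE (synthetic minority oversampling) is implemented here: each synthetic
minority row is a convex combination of a minority row and one of its
*k* nearest minority neighbors on the feature vector, with categorical
(binary) features copied from the seed row.  By default rebalancing happens
inside each cross-validation fold so that no validation-fold information
reaches the oversampler; a compatibility flag rebalances once up front
instead.

Leakage is guarded explicitly: the selected threshold carries a provenance
tag and evaluation refuses thresholds not selected on training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

FAMILIES = ("random_forest", "gradient_boosted_trees", "support_vector_machine")

#: Default hyperparameter grids per family.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "random_forest": [
        {"n_estimators": n, "max_depth": d}
        for n in (200, 500)
        for d in (3, 6, None)
    ],
    "gradient_boosted_trees": [
        {"n_estimators": n, "max_depth": d, "learning_rate": lr}
        for n in (200, 500)
        for d in (3, 6)
        for lr in (0.05, 0.1)
    ],
    "support_vector_machine": [{"C": c} for c in (0.1, 1.0, 10.0)],
}

#: Feature columns used for modelling (everything but identifiers/outcome).
ID_COLUMNS = ("patient_id", "outcome")


class LeakageError(RuntimeError):
    """Test-set information reached a training-only step."""


def feature_columns(rows: pd.DataFrame) -> list[str]:
    return [c for c in rows.columns if c not in ID_COLUMNS]


# --------------------------------------------------------------------------
# stratified split
# --------------------------------------------------------------------------


def stratified_split(
    rows: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    outcome: str = "outcome",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """80/20 train/test split stratified on the outcome, seeded.

    The outcome proportion in train and test differs by less than one
    patient's worth; rerunning with the same seed reproduces the split.
    """
    counts = rows[outcome].value_counts()
    if len(counts) < 2:
        raise ValueError("both outcome classes must be present to split")
    if counts.min() < 2:
        raise ValueError(
            f"outcome class {counts.idxmin()!r} has {counts.min()} member(s); need >= 2"
        )
    train, test = train_test_split(
        rows,
        test_size=test_fraction,
        stratify=rows[outcome],
        random_state=seed,
        shuffle=True,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


# --------------------------------------------------------------------------
# SMOTE
# --------------------------------------------------------------------------


def smote(
    train: pd.DataFrame,
    k_neighbors: int = 5,
    seed: int = 0,
    outcome: str = "outcome",
    categorical: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Synthetic minority oversampling to equal class counts.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``,
    where ``x_nn`` is one of the *k* nearest minority neighbors of minority
    seed row ``x_i`` (Euclidean distance on the feature vector).  Categorical
    features — by default every all-binary column — are copied from the seed
    row instead of interpolated.  Already-balanced input is returned
    unchanged.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    counts = train[outcome].value_counts()
    if len(counts) < 2:
        raise ValueError("both outcome classes must be present")
    minority_label = counts.idxmin()
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return train
    if n_min < k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} members; needs >= k_neighbors + 1 = "
            f"{k_neighbors + 1} (use a smaller k_neighbors)"
        )
    feats = feature_columns(train)
    if categorical is None:
        categorical = [
            c for c in feats if set(np.unique(train[c].to_numpy())) <= {0, 1}
        ]
    minority = train[train[outcome] == minority_label]
    X = minority[feats].to_numpy(dtype=float)

    # pairwise distances among minority rows; self excluded
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbor_idx = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]

    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    seeds = rng.integers(0, len(X), size=n_new)
    picks = rng.integers(0, k_neighbors, size=n_new)
    gaps = rng.random(n_new)

    synth_rows = []
    for i, j, u in zip(seeds, picks, gaps):
        nn = neighbor_idx[i, j]
        vec = X[i] + u * (X[nn] - X[i])
        row = dict(zip(feats, vec))
        for c in categorical:
            row[c] = minority.iloc[i][c]
        row[outcome] = minority_label
        if "patient_id" in train.columns:
            row["patient_id"] = f"synthetic_{minority.iloc[i]['patient_id']}_{len(synth_rows)}"
        synth_rows.append(row)
    out = pd.concat([train, pd.DataFrame(synth_rows)], ignore_index=True)
    return out[train.columns]


# --------------------------------------------------------------------------
# model construction and CV tuning
# --------------------------------------------------------------------------


def _make_model(family: str, params: Mapping, seed: int):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "gradient_boosted_trees":
        return XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
            tree_method="hist",
            **params,
        )
    if family == "support_vector_machine":
        return SVC(kernel="rbf", random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


@dataclass
class FittedModel:
    family: str
    model: object
    best_params: dict
    cv_results: pd.DataFrame  # one row per grid point: params, mean/std CV AUC
    features: list[str]
    scaler: StandardScaler | None = None

    def predict_scores(self, rows: pd.DataFrame) -> np.ndarray:
        """Continuous bleeding-risk scores (higher = more likely ADE)."""
        X = rows[self.features].to_numpy(dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        if hasattr(self.model, "predict_proba"):
            return self.model.predict_proba(X)[:, 1]
        return self.model.decision_function(X)


def tune_and_train(
    train: pd.DataFrame,
    family: str,
    grid: Sequence[Mapping] | None = None,
    folds: int = 10,
    seed: int = 0,
    outcome: str = "outcome",
    smote_in_fold: bool = True,
    k_neighbors: int = 5,
) -> FittedModel:
    """10-fold cross-validated hyperparameter tuning and final refit.

    Hyperparameters are chosen by maximal mean cross-validated ROC AUC with
    stratified, seeded folds; the winning configuration is refit on the full
    SMOTE-rebalanced training sample.  With ``smote_in_fold=True`` (default)
    rebalancing is applied to each fold's training part only, so validation
    folds stay untouched by the oversampler; ``False`` rebalances the whole
    training sample once before cross-validation (compatibility mode).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    grid = list(grid if grid is not None else DEFAULT_GRIDS[family])
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    feats = feature_columns(train)
    needs_scaling = family == "support_vector_machine"

    cv_train = train if smote_in_fold else smote(train, k_neighbors, seed, outcome)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_all = cv_train[outcome].to_numpy()

    records = []
    from sklearn.metrics import roc_auc_score

    for params in grid:
        fold_aucs = []
        for fold_train_idx, fold_val_idx in skf.split(cv_train[feats], y_all):
            fold_train = cv_train.iloc[fold_train_idx]
            fold_val = cv_train.iloc[fold_val_idx]
            if smote_in_fold:
                fold_train = smote(fold_train, k_neighbors, seed, outcome)
            scaler = None
            Xtr = fold_train[feats].to_numpy(dtype=float)
            Xva = fold_val[feats].to_numpy(dtype=float)
            if needs_scaling:
                scaler = StandardScaler().fit(Xtr)
                Xtr, Xva = scaler.transform(Xtr), scaler.transform(Xva)
            model = _make_model(family, params, seed)
            model.fit(Xtr, fold_train[outcome].to_numpy())
            if hasattr(model, "predict_proba"):
                scores = model.predict_proba(Xva)[:, 1]
            else:
                scores = model.decision_function(Xva)
            fold_aucs.append(roc_auc_score(fold_val[outcome].to_numpy(), scores))
        records.append(
            {"params": dict(params), "mean_cv_auc": float(np.mean(fold_aucs)),
             "std_cv_auc": float(np.std(fold_aucs))}
        )
    cv_results = pd.DataFrame(records)
    best = cv_results.loc[cv_results["mean_cv_auc"].idxmax()]
    best_params = dict(best["params"])

    final_train = smote(train, k_neighbors, seed, outcome)
    scaler = None
    Xtr = final_train[feats].to_numpy(dtype=float)
    if needs_scaling:
        scaler = StandardScaler().fit(Xtr)
        Xtr = scaler.transform(Xtr)
    model = _make_model(family, best_params, seed)
    model.fit(Xtr, final_train[outcome].to_numpy())
    return FittedModel(
        family=family,
        model=model,
        best_params=best_params,
        cv_results=cv_results,
        features=feats,
        scaler=scaler,
    )


# --------------------------------------------------------------------------
# threshold selection
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Threshold:
    value: float
    provenance: str  # "train" or "test"; evaluation refuses "test"
    distance: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")


def select_threshold(
    scores: np.ndarray, labels: np.ndarray, provenance: str = "train"
) -> Threshold:
    """Operating point minimizing the ROC distance to the ideal (1, 1).

    Candidates are the observed score cut-points (predict positive when
    score ≥ cut-point).  The cut-point minimizing
    ``sqrt((1 − sensitivity)² + (1 − specificity)²)`` wins; ties break toward
    higher sensitivity, then toward the lower cut-point.  Constant scores
    yield the single degenerate cut-point with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to select a threshold")
    candidates = np.unique(scores)
    if len(candidates) == 1:
        warnings.warn("constant scores: returning the single degenerate cut-point")
    pos = labels == classes.max()
    best: Threshold | None = None
    for cut in candidates:
        pred = scores >= cut
        sens = float((pred & pos).sum() / pos.sum())
        spec = float((~pred & ~pos).sum() / (~pos).sum())
        dist = float(np.hypot(1 - sens, 1 - spec))
        cand = Threshold(float(cut), provenance, dist, sens, spec)
        if (
            best is None
            or dist < best.distance
            or (dist == best.distance and sens > best.sensitivity)
            or (dist == best.distance and sens == best.sensitivity and cut < best.value)
        ):
            best = cand
    assert best is not None
    return best


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


@dataclass
class EvalReport:
    family: str
    accuracy: float
    sensitivity: float
    specificity: float
    roc_auc: float
    threshold: float

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc_auc": self.roc_auc,
            "threshold": self.threshold,
        }


def roc_auc_trapezoidal(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by trapezoidal integration over unique score cut-points."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def evaluate(
    model: FittedModel, test: pd.DataFrame, threshold: Threshold, outcome: str = "outcome"
) -> EvalReport:
    """Accuracy, sensitivity, specificity at the chosen threshold, plus AUC.

    The threshold must have been selected on training data: a threshold with
    provenance other than ``"train"`` is refused (leakage guard).
    """
    if threshold.provenance != "train":
        raise LeakageError(
            f"threshold provenance {threshold.provenance!r} != 'train': "
            "operating points must be selected on training data only"
        )
    y = test[outcome].to_numpy()
    scores = model.predict_scores(test)
    pred = scores >= threshold.value
    pos = y == 1
    sens = float((pred & pos).sum() / pos.sum()) if pos.any() else float("nan")
    spec = float((~pred & ~pos).sum() / (~pos).sum()) if (~pos).any() else float("nan")
    acc = float((pred == pos).mean())
    return EvalReport(
        family=model.family,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        roc_auc=roc_auc_trapezoidal(y, scores),
        threshold=threshold.value,
    )


# --------------------------------------------------------------------------
# variable importance
# --------------------------------------------------------------------------


def variable_importance(fitted: FittedModel) -> pd.DataFrame:
    """Gain-based importances, normalized to sum 1, descending.

    Available for tree-ensemble families only: gradient-boosted trees report
    the total performance gain accrued each time a variable is used; random
    forests report impurity-decrease importances.
    """
    if fitted.family == "gradient_boosted_trees":
        booster = fitted.model.get_booster()
        gains = booster.get_score(importance_type="gain")
        raw = np.array(
            [gains.get(f"f{i}", 0.0) for i in range(len(fitted.features))], dtype=float
        )
    elif fitted.family == "random_forest":
        raw = np.asarray(fitted.model.feature_importances_, dtype=float)
    else:
        raise ValueError("variable importance requires a tree-ensemble model")
    total = raw.sum()
    norm = raw / total if total > 0 else raw
    df = pd.DataFrame({"feature": fitted.features, "importance": norm})
    return df.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# end-to-end convenience
# --------------------------------------------------------------------------


def run_ml_workflow(
    rows: pd.DataFrame,
    family: str = "gradient_boosted_trees",
    grid: Sequence[Mapping] | None = None,
    folds: int = 10,
    seed: int = 0,
    test_fraction: float = 0.2,
    smote_in_fold: bool = True,
) -> tuple[FittedModel, Threshold, EvalReport]:
    """Split, rebalance, tune, select the operating point and evaluate."""
    train, test = stratified_split(rows, test_fraction, seed)
    fitted = tune_and_train(
        train, family, grid=grid, folds=folds, seed=seed, smote_in_fold=smote_in_fold
    )
    threshold = select_threshold(
        fitted.predict_scores(train), train["outcome"].to_numpy(), provenance="train"
    )
    report = evaluate(fitted, test, threshold)
    return fitted, threshold, report
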