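"""Gaussian-kernel SVM classification of Ab-positivity with cross-validation.

The classifier is an RBF-kernel SVM evaluated by stratified fivefold
cross-validation, with a grid search over the SVM hyperparameters C and
gamma and over the number of independent components K.  Two tuning modes
are provided:

* ``nested`` (default) — within every outer training fold, the ICA, the
  feature scaling, and the (C, gamma, K) grid search are refit from scratch
  using only that fold's training subjects, so no statistic of the held-out
  subjects can leak into the fitted model;
* ``pooled`` — the ICA is fit once on all scans per candidate K and the
  grid search maximizes plain fivefold CV accuracy, reproducing the original
  all-scans protocol.

All reported metrics pool out-of-fold predictions: each subject is predicted
exactly once, by the model of the fold that held it out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .decompose import decompose, estimate_loadings
from .features import FeatureSetSpec, assemble_features
from .volumes import BrainMask, FlatMatrix, flatten_volumes

__all__ = [
    "CVConfig",
    "PredictionSet",
    "MetricsReport",
    "crossval_fit_predict",
    "compute_metrics",
    "breakdown_by_diagnosis",
    "ablation",
    "DIAGNOSIS_SUBSETS",
    "KNOWN_DIAGNOSES",
]

KNOWN_DIAGNOSES = {"AD", "MCI", "FTLD", "CBS", "PSP", "Psychiatric", "HC"}

#: Diagnosis subsets of the per-diagnosis performance breakdown.
DIAGNOSIS_SUBSETS: dict[str, tuple[str, ...]] = {
    "HC": ("HC",),
    "AD": ("AD",),
    "HC+AD": ("HC", "AD"),
    "MCI": ("MCI",),
    "HC+MCI": ("HC", "MCI"),
    "HC+MCI+AD": ("HC", "MCI", "AD"),
    "FTLD": ("FTLD",),
    "CBS": ("CBS",),
    "PSP": ("PSP",),
    "Psychiatric": ("Psychiatric",),
    "ALL": tuple(sorted(KNOWN_DIAGNOSES)),
}

_DECADES = tuple(float(10.0**e) for e in range(-3, 4))


@dataclass
class CVConfig:
    """Cross-validation and grid-search settings.

    Default grids span decades for C and gamma and K = 2..12, which covers
    the reference optimum (C=0.01, gamma=100, K=7).  ``n_inner`` controls
    the inner split count of the nested search.
    """

    n_folds: int = 5
    stratified: bool = True
    seed: int = 0
    tuning_mode: str = "nested"
    c_grid: tuple[float, ...] = _DECADES
    gamma_grid: tuple[float, ...] = _DECADES
    k_grid: tuple[int, ...] = tuple(range(2, 13))
    n_inner: int = 3

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.tuning_mode not in ("nested", "pooled"):
            raise ValueError("tuning_mode must be 'nested' or 'pooled'")
        for name in ("c_grid", "gamma_grid", "k_grid"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")


@dataclass
class PredictionSet:
    """Pooled out-of-fold predictions with the provenance needed for SHAP."""

    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    fold_index: np.ndarray
    chosen_params: list[dict]
    feature_names: list[str]
    models: list[Pipeline] = field(default_factory=list, repr=False)
    fold_train_X: list[pd.DataFrame] = field(default_factory=list, repr=False)
    fold_test_X: list[pd.DataFrame] = field(default_factory=list, repr=False)
    spec_name: str = ""
    tuning_mode: str = ""

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for name in ("y_true", "y_pred", "scores", "fold_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match subjects")

    @property
    def n_folds(self) -> int:
        return int(self.fold_index.max()) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "y_true": self.y_true,
            "y_pred": self.y_pred,
            "score": self.scores,
            "fold": self.fold_index,
        })


@dataclass
class MetricsReport:
    """Confusion counts and derived performance metrics for one subset.

    Ratios follow  accuracy = (TP+TN)/(TP+TN+FN+FP),  sensitivity =
    TP/(TP+FN),  specificity = TN/(FP+TN),  PPV = TP/(TP+FP),  NPV =
    TN/(FN+TN),  expressed in percent.  A ratio with a zero denominator is
    NaN and prints as "N/A" (never as 0).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    auc_ci: tuple[float, float]
    n: int
    subset_name: str = "ALL"

    def to_dict(self) -> dict:
        return {
            "subset": self.subset_name, "n": self.n,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv,
            "npv": self.npv, "auc": self.auc, "auc_ci": self.auc_ci,
        }

    def formatted(self) -> dict:
        def pct(x):
            return "N/A" if x is None or np.isnan(x) else f"{x:.1f}"
        return {
            "subset": self.subset_name, "n": self.n,
            "accuracy": pct(self.accuracy),
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "ppv": pct(self.ppv), "npv": pct(self.npv),
            "auc": "N/A" if np.isnan(self.auc) else f"{self.auc:.3f}",
        }


def _labels_to_binary(table: pd.DataFrame) -> np.ndarray:
    if "ab_label" not in table.columns:
        raise ValueError("subject table lacks 'ab_label'")
    return (table["ab_label"].to_numpy() == "positive").astype(int)


def _add_missing_indicators(X: pd.DataFrame) -> pd.DataFrame:
    """Companion indicator column for every feature containing NaN."""
    out = X.copy()
    for col in X.columns[X.isna().any(axis=0)]:
        out[f"{col}__missing"] = X[col].isna().astype(float)
    return out


def _make_pipeline(C: float, gamma: float) -> Pipeline:
    return Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", C=C, gamma=gamma)),
    ])


def _splitter(cv: CVConfig, seed: int, n_folds: int):
    if cv.stratified:
        return StratifiedKFold(n_splits=n_folds, shuffle=True,
                               random_state=seed)
    return KFold(n_splits=n_folds, shuffle=True, random_state=seed)


def _check_folds(y: np.ndarray, splits, stratified: bool) -> None:
    import warnings as _warnings
    for _, (tr, te) in enumerate(splits):
        if len(np.unique(y[tr])) < 2:
            msg = "a training fold contains a single class"
            if stratified:
                raise ValueError(msg)
            _warnings.warn(msg)


def _grid_iter(cv: CVConfig, use_brain: bool):
    k_values = cv.k_grid if use_brain else (None,)
    for K in k_values:
        for gamma in cv.gamma_grid:
            for C in cv.c_grid:
                yield K, gamma, C


def _fold_features(
    matrix: FlatMatrix | None,
    table: pd.DataFrame,
    spec: FeatureSetSpec,
    K: int | None,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
):
    """Assemble train/test feature frames with fold-internal ICA."""
    if K is not None:
        sub = FlatMatrix(
            data=matrix.data[train_idx],
            voxel_index=matrix.voxel_index,
            grid_shape=matrix.grid_shape,
            subject_ids=[matrix.subject_ids[i] for i in train_idx],
        )
        comp = decompose(sub, K, seed=seed)
        loadings = np.empty((len(table), K))
        loadings[train_idx] = comp.loadings
        test_matrix = FlatMatrix(
            data=matrix.data[test_idx],
            voxel_index=matrix.voxel_index,
            grid_shape=matrix.grid_shape,
            subject_ids=[matrix.subject_ids[i] for i in test_idx],
        )
        loadings[test_idx] = estimate_loadings(test_matrix, comp)
        X = assemble_features(loadings, table, spec)
    else:
        X = assemble_features(None, table, spec)
    X = _add_missing_indicators(X)
    return X.iloc[train_idx], X.iloc[test_idx]


def crossval_fit_predict(
    matrix_or_volumes,
    table: pd.DataFrame,
    spec: FeatureSetSpec | str,
    cv: CVConfig,
    mask: BrainMask | None = None,
) -> PredictionSet:
    """Grid-searched SVM with out-of-fold predictions for every subject.

    See the module docstring for the two tuning modes.  Ties in the grid
    search are broken by grid order (K, then gamma, then C, first listed
    wins).  Fully deterministic for a fixed ``cv.seed``.
    """
    if isinstance(spec, str):
        spec = FeatureSetSpec(spec)
    use_brain = "brain" in spec.blocks
    matrix: FlatMatrix | None = None
    if use_brain:
        if isinstance(matrix_or_volumes, FlatMatrix):
            matrix = matrix_or_volumes
        else:
            if mask is None:
                raise ValueError("a BrainMask is required with raw volumes")
            matrix = flatten_volumes(matrix_or_volumes, mask)

    y = _labels_to_binary(table)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 subjects per class")

    outer = list(
        _splitter(cv, cv.seed, cv.n_folds).split(np.zeros_like(y), y)
    )
    _check_folds(y, outer, cv.stratified)

    if cv.tuning_mode == "pooled":
        return _fit_pooled(matrix, table, spec, cv, y, outer, use_brain)
    return _fit_nested(matrix, table, spec, cv, y, outer, use_brain)


def _grid_accuracy(train_X, train_y, val_X, val_y, cv: CVConfig):
    """Accuracy of every (gamma, C) cell on one prepared split."""
    prep = Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
    ])
    Xt = prep.fit_transform(train_X)
    Xv = prep.transform(val_X)
    acc = np.zeros((len(cv.gamma_grid), len(cv.c_grid)))
    for gi, gamma in enumerate(cv.gamma_grid):
        for ci, C in enumerate(cv.c_grid):
            svc = SVC(kernel="rbf", C=C, gamma=gamma)
            svc.fit(Xt, train_y)
            acc[gi, ci] = (svc.predict(Xv) == val_y).mean()
    return acc


def _argmax_grid(acc: np.ndarray) -> tuple[int, ...]:
    """First strict maximum in C-order iteration (grid-order tie-break)."""
    flat = np.argmax(acc)  # np.argmax returns the first maximum in C order
    return np.unravel_index(flat, acc.shape)


def _fit_nested(matrix, table, spec, cv, y, outer, use_brain):
    n = len(table)
    y_pred = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    fold_index = np.empty(n, dtype=int)
    chosen, models, train_Xs, test_Xs = [], [], [], []
    k_values = cv.k_grid if use_brain else (None,)

    for f, (train_idx, test_idx) in enumerate(outer):
        inner_seed = cv.seed + 1000 * (f + 1)
        inner = list(
            _splitter(cv, inner_seed, cv.n_inner).split(
                np.zeros_like(y[train_idx]), y[train_idx]
            )
        )
        acc = np.zeros((len(k_values), len(cv.gamma_grid), len(cv.c_grid)))
        for ii, (itr, ite) in enumerate(inner):
            g_itr = train_idx[itr]
            g_ite = train_idx[ite]
            for ki, K in enumerate(k_values):
                tX, vX = _fold_features(
                    matrix, table, spec, K, g_itr, g_ite,
                    seed=inner_seed + ii,
                )
                acc[ki] += _grid_accuracy(tX, y[g_itr], vX, y[g_ite], cv)
        acc /= len(inner)
        ki, gi, ci = _argmax_grid(acc)
        K, gamma, C = k_values[ki], cv.gamma_grid[gi], cv.c_grid[ci]

        train_X, test_X = _fold_features(
            matrix, table, spec, K, train_idx, test_idx, seed=cv.seed
        )
        model = _make_pipeline(C, gamma)
        model.fit(train_X, y[train_idx])
        y_pred[test_idx] = model.predict(test_X)
        scores[test_idx] = model.decision_function(test_X)
        fold_index[test_idx] = f
        chosen.append({"C": C, "gamma": gamma, "K": K,
                       "inner_cv_accuracy": float(acc[ki, gi, ci])})
        models.append(model)
        train_Xs.append(train_X)
        test_Xs.append(test_X)

    return PredictionSet(
        subject_ids=list(table["subject_id"]),
        y_true=y, y_pred=y_pred, scores=scores, fold_index=fold_index,
        chosen_params=chosen,
        feature_names=list(train_Xs[0].columns),
        models=models, fold_train_X=train_Xs, fold_test_X=test_Xs,
        spec_name=spec.name, tuning_mode="nested",
    )


def _fit_pooled(matrix, table, spec, cv, y, outer, use_brain):
    n = len(table)
    # ICA once on all scans per candidate K (original protocol)
    features_by_K: dict = {}
    k_values = cv.k_grid if use_brain else (None,)
    for K in k_values:
        if K is None:
            X = assemble_features(None, table, spec)
        else:
            comp = decompose(matrix, K, seed=cv.seed)
            X = assemble_features(comp.loadings, table, spec)
        features_by_K[K] = _add_missing_indicators(X)

    best = None
    for K in k_values:
        X = features_by_K[K]
        acc = np.zeros((len(cv.gamma_grid), len(cv.c_grid)))
        for train_idx, test_idx in outer:
            acc += _grid_accuracy(
                X.iloc[train_idx], y[train_idx],
                X.iloc[test_idx], y[test_idx], cv,
            )
        acc /= len(outer)
        gi, ci = _argmax_grid(acc)
        if best is None or acc[gi, ci] > best["acc"]:
            best = {"acc": acc[gi, ci], "K": K,
                    "gamma": cv.gamma_grid[gi], "C": cv.c_grid[ci]}

    X = features_by_K[best["K"]]
    y_pred = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    fold_index = np.empty(n, dtype=int)
    chosen, models, train_Xs, test_Xs = [], [], [], []
    for f, (train_idx, test_idx) in enumerate(outer):
        model = _make_pipeline(best["C"], best["gamma"])
        model.fit(X.iloc[train_idx], y[train_idx])
        y_pred[test_idx] = model.predict(X.iloc[test_idx])
        scores[test_idx] = model.decision_function(X.iloc[test_idx])
        fold_index[test_idx] = f
        chosen.append({"C": best["C"], "gamma": best["gamma"],
                       "K": best["K"],
                       "cv_accuracy": float(best["acc"])})
        models.append(model)
        train_Xs.append(X.iloc[train_idx])
        test_Xs.append(X.iloc[test_idx])

    return PredictionSet(
        subject_ids=list(table["subject_id"]),
        y_true=y, y_pred=y_pred, scores=scores, fold_index=fold_index,
        chosen_params=chosen, feature_names=list(X.columns),
        models=models, fold_train_X=train_Xs, fold_test_X=test_Xs,
        spec_name=spec.name, tuning_mode="pooled",
    )


def _safe_ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def compute_metrics(
    predictions: PredictionSet | None = None,
    labels: np.ndarray | None = None,
    *,
    y_pred: np.ndarray | None = None,
    scores: np.ndarray | None = None,
    subset: np.ndarray | None = None,
    subset_name: str = "ALL",
    n_boot: int = 2000,
    seed: int = 0,
) -> MetricsReport:
    """Confusion counts, ratio metrics, and AUC for a subject subset.

    Accepts either a :class:`PredictionSet` (optionally restricted by the
    boolean ``subset`` mask) or raw ``labels`` / ``y_pred`` / ``scores``
    arrays.  The AUC comes from pooled out-of-fold decision scores with a
    seeded percentile bootstrap CI (``n_boot`` resamples).
    """
    if predictions is not None:
        y_true = predictions.y_true
        y_hat = predictions.y_pred
        sc = predictions.scores
    else:
        y_true = np.asarray(labels)
        y_hat = np.asarray(y_pred)
        sc = np.asarray(scores, dtype=float) if scores is not None else None
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        y_true, y_hat = y_true[subset], y_hat[subset]
        sc = sc[subset] if sc is not None else None
    if len(y_true) != len(y_hat):
        raise ValueError("predictions and labels are not aligned")

    n = len(y_true)
    tp = int(np.sum((y_true == 1) & (y_hat == 1)))
    tn = int(np.sum((y_true == 0) & (y_hat == 0)))
    fp = int(np.sum((y_true == 0) & (y_hat == 1)))
    fn = int(np.sum((y_true == 1) & (y_hat == 0)))

    auc = float("nan")
    ci = (float("nan"), float("nan"))
    if sc is not None and n > 0 and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, sc))
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            boots = []
            for _ in range(n_boot):
                idx = rng.integers(0, n, n)
                if len(np.unique(y_true[idx])) < 2:
                    continue
                boots.append(roc_auc_score(y_true[idx], sc[idx]))
            if boots:
                ci = (float(np.percentile(boots, 2.5)),
                      float(np.percentile(boots, 97.5)))

    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_safe_ratio(tp + tn, n),
        sensitivity=_safe_ratio(tp, tp + fn),
        specificity=_safe_ratio(tn, fp + tn),
        ppv=_safe_ratio(tp, tp + fp),
        npv=_safe_ratio(tn, fn + tn),
        auc=auc, auc_ci=ci, n=n, subset_name=subset_name,
    )


def breakdown_by_diagnosis(
    predictions: PredictionSet,
    table: pd.DataFrame,
    subsets: dict[str, tuple[str, ...]] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> list[MetricsReport]:
    """Metrics on diagnosis subsets of the SAME out-of-fold predictions.

    No refitting happens: each subset report restricts the pooled
    predictions to subjects whose diagnosis falls in the subset.
    """
    if "diagnosis" not in table.columns:
        raise ValueError("subject table lacks 'diagnosis'")
    if subsets is None:
        subsets = DIAGNOSIS_SUBSETS
    diag = table["diagnosis"].to_numpy()
    reports = []
    for name, members in subsets.items():
        unknown = set(members) - KNOWN_DIAGNOSES
        if unknown:
            raise ValueError(f"unknown diagnosis names in {name!r}: {unknown}")
        mask = np.isin(diag, list(members))
        reports.append(compute_metrics(
            predictions, subset=mask, subset_name=name,
            n_boot=n_boot, seed=seed,
        ))
    return reports


def ablation(
    matrix_or_volumes,
    table: pd.DataFrame,
    specs: list[FeatureSetSpec | str],
    cv: CVConfig,
    mask: BrainMask | None = None,
    n_boot: int = 2000,
) -> tuple[pd.DataFrame, dict[str, PredictionSet]]:
    """One full cross-validated fit + metrics per feature set.

    Returns a report frame with one row per feature set (in the given
    order) and the underlying prediction sets keyed by spec name.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rows, preds = [], {}
    for raw in specs:
        spec = FeatureSetSpec(raw) if isinstance(raw, str) else raw
        ps = crossval_fit_predict(matrix_or_volumes, table, spec, cv,
                                  mask=mask)
        rep = compute_metrics(ps, subset_name=spec.name, n_boot=n_boot,
                              seed=cv.seed)
        row = rep.to_dict()
        row["feature_set"] = spec.name
        rows.append(row)
        preds[spec.name] = ps
    report = pd.DataFrame(rows).set_index("feature_set")
    return report, preds
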