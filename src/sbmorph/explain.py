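"""Shapley-value attribution of the SVM decision score.

Model-agnostic kernel-based Shapley estimation: for each explained subject,
feature coalitions are drawn (or fully enumerated when feasible), the model
is evaluated with coalition features taken from the subject and the
remaining features marginalized over a background sample from the training
fold, and attributions are recovered by the Shapley-kernel-weighted least
squares with the efficiency constraint

    base_value + sum_j phi_j = f(x).

Attributions explain the SVM decision function (the signed distance to the
separating surface), not the hard label: positive phi push the subject
toward the Ab-positive side.  With full coalition enumeration (the default
whenever 2^M does not exceed the coalition budget) the solution is the exact
Shapley value of the marginalized value function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import binom

from .classify import PredictionSet

__all__ = [
    "ShapMatrix",
    "kernel_shap",
    "shap_values",
    "shap_for_predictions",
    "mean_abs_importance",
    "beeswarm_export",
]

#: Default coalition budget per explained subject.
DEFAULT_N_COALITIONS = 2**11

#: Default cap on background rows drawn from the training fold.
DEFAULT_BACKGROUND_SIZE = 100


@dataclass
class ShapMatrix:
    """Per-subject, per-feature attributions for one fold's model."""

    values: np.ndarray
    base_value: float
    feature_names: list[str]
    fold_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("SHAP values must be 2D (subjects x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")


def _coalition_matrix(M: int, n_coalitions: int, rng: np.random.Generator):
    """Coalition indicator matrix and Shapley-kernel weights.

    Enumerates all 2^M - 2 proper coalitions when they fit in the budget;
    otherwise draws paired samples (z and its complement) with probability
    proportional to the kernel weight of the coalition size.
    """
    kernel = np.array([
        (M - 1) / (binom(M, s) * s * (M - s)) for s in range(1, M)
    ])  # weight of one coalition of size s

    if 2**M - 2 <= n_coalitions:
        Z = np.array(
            [[(i >> j) & 1 for j in range(M)] for i in range(1, 2**M - 1)],
            dtype=float,
        )
        sizes = Z.sum(axis=1).astype(int)
        w = kernel[sizes - 1]
        return Z, w

    size_prob = kernel * binom(M, np.arange(1, M))
    size_prob /= size_prob.sum()
    n_pairs = n_coalitions // 2
    rows = np.zeros((2 * n_pairs, M))
    for i in range(n_pairs):
        s = 1 + rng.choice(M - 1, p=size_prob)
        members = rng.choice(M, size=s, replace=False)
        rows[2 * i, members] = 1.0
        rows[2 * i + 1] = 1.0 - rows[2 * i]
    # sampled coalitions are equally weighted (importance sampling)
    return rows, np.ones(len(rows))


def kernel_shap(
    predict_fn,
    background: np.ndarray,
    X: np.ndarray,
    seed: int = 0,
    n_coalitions: int = DEFAULT_N_COALITIONS,
) -> tuple[np.ndarray, float]:
    """Shapley attributions of ``predict_fn`` for each row of ``X``.

    ``predict_fn`` maps an (n, M) array to n real scores.  Marginalization
    of absent features averages over ``background`` rows.  Returns
    ``(phi, base_value)`` with ``phi`` of shape (len(X), M) satisfying
    ``base_value + phi.sum(1) == predict_fn(X)`` (exactly under full
    enumeration, to Monte-Carlo tolerance under sampling).
    """
    background = np.asarray(background, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if background.ndim != 2 or background.shape[1] != X.shape[1]:
        raise ValueError(
            "background and X must share the feature dimension"
        )
    M = X.shape[1]
    rng = np.random.default_rng(seed)
    base = float(np.mean(predict_fn(background)))

    if M == 1:
        fx = np.asarray(predict_fn(X), dtype=float)
        return (fx - base).reshape(-1, 1), base

    Z, w = _coalition_matrix(M, n_coalitions, rng)
    n_z, n_bg = len(Z), len(background)

    fx = np.asarray(predict_fn(X), dtype=float)
    phi = np.empty((len(X), M))
    for i, x in enumerate(X):
        # synthetic rows: coalition features from x, the rest from background
        synth = np.where(
            Z[:, None, :].astype(bool),
            x[None, None, :],
            background[None, :, :],
        ).reshape(n_z * n_bg, M)
        v = predict_fn(synth).reshape(n_z, n_bg).mean(axis=1)
        phi[i] = _solve_constrained_wls(Z, w, v - base, fx[i] - base)
    return phi, base


def _solve_constrained_wls(Z, w, y, total):
    """Weighted least squares with the efficiency constraint sum(phi)=total.

    The last feature is eliminated through the constraint, which is the
    standard reduction for the Shapley kernel (whose end-point coalitions
    carry infinite weight).
    """
    M = Z.shape[1]
    Zr = Z[:, :-1] - Z[:, -1:]
    yr = y - Z[:, -1] * total
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(Zr * sw[:, None], yr * sw, rcond=None)
    phi = np.empty(M)
    phi[:-1] = beta
    phi[-1] = total - beta.sum()
    return phi


def shap_values(
    model,
    background: np.ndarray | pd.DataFrame,
    samples: np.ndarray | pd.DataFrame,
    seed: int = 0,
    n_coalitions: int = DEFAULT_N_COALITIONS,
    max_background: int = DEFAULT_BACKGROUND_SIZE,
    feature_names: list[str] | None = None,
    fold_index: int = 0,
) -> ShapMatrix:
    """Kernel-SHAP attributions of a fitted model's decision score.

    ``model`` must expose ``decision_function`` (fallback: ``predict``).
    ``background`` is subsampled to at most ``max_background`` rows
    (seeded) before marginalization.
    """
    if isinstance(background, pd.DataFrame):
        if feature_names is None:
            feature_names = list(background.columns)
        background = background.to_numpy(dtype=float)
    if isinstance(samples, pd.DataFrame):
        samples = samples.to_numpy(dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(samples.shape[1])]
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if samples.shape[1] != background.shape[1]:
        raise ValueError("feature count mismatch between samples/background")

    rng = np.random.default_rng(seed)
    if len(background) > max_background:
        keep = rng.choice(len(background), max_background, replace=False)
        background = background[keep]

    predict = getattr(model, "decision_function", None) or model.predict
    if hasattr(model, "feature_names_in_"):
        # fitted on a DataFrame: silence feature-name checks
        names = list(model.feature_names_in_)

        def predict(A, _raw=getattr(model, "decision_function", model.predict)):
            return _raw(pd.DataFrame(A, columns=names))

    phi, base = kernel_shap(
        predict, background, samples, seed=seed, n_coalitions=n_coalitions
    )
    return ShapMatrix(values=phi, base_value=base,
                      feature_names=list(feature_names),
                      fold_index=fold_index)


def shap_for_predictions(
    predictions: PredictionSet,
    seed: int = 0,
    n_coalitions: int = DEFAULT_N_COALITIONS,
    max_background: int = DEFAULT_BACKGROUND_SIZE,
) -> list[ShapMatrix]:
    """One ShapMatrix per CV fold: each fold's model explained on its
    held-out subjects against its own training-fold background."""
    out = []
    for f, model in enumerate(predictions.models):
        out.append(shap_values(
            model,
            predictions.fold_train_X[f],
            predictions.fold_test_X[f],
            seed=seed + f,
            n_coalitions=n_coalitions,
            max_background=max_background,
            feature_names=list(predictions.fold_train_X[f].columns),
            fold_index=f,
        ))
    return out


def mean_abs_importance(
    shap_per_fold: list[ShapMatrix], allow_union: bool = False
) -> pd.Series:
    """Mean over folds of the mean |phi| over each fold's subjects.

    Sorted descending; ties broken by feature name.  This is the ranking
    behind a fold-averaged SHAP importance bar plot.  Folds must share one
    feature set; with ``allow_union=True`` (nested tuning can select a
    different K per fold) each feature is averaged over the folds that
    contain it.
    """
    if not shap_per_fold:
        raise ValueError("need at least one fold")
    names = shap_per_fold[0].feature_names
    if not allow_union:
        for sm in shap_per_fold[1:]:
            if sm.feature_names != names:
                raise ValueError("inconsistent feature sets across folds")
    per_fold = [
        pd.Series(np.abs(sm.values).mean(axis=0), index=sm.feature_names)
        for sm in shap_per_fold
    ]
    imp = pd.concat(per_fold, axis=1).mean(axis=1, skipna=True)
    imp.name = "mean_abs_shap"
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return imp.loc[order]


def beeswarm_export(
    shap_per_fold: list[ShapMatrix],
    features_per_fold: list[pd.DataFrame],
) -> pd.DataFrame:
    """Long-format table for beeswarm-style plots.

    One row per (subject, fold, feature) with the attribution, the raw
    feature value, its within-export percentile, and a direction flag
    ("toward Ab-positive" for positive phi).  Lossless: pivoting the phi
    column back reproduces each fold's ShapMatrix.
    """
    if len(shap_per_fold) != len(features_per_fold):
        raise ValueError("one feature frame per ShapMatrix required")
    rows = []
    all_vals = pd.concat(features_per_fold, axis=0)
    pct = all_vals.rank(pct=True)
    offset = 0
    for sm, feats in zip(shap_per_fold, features_per_fold):
        if sm.values.shape != feats.shape:
            raise ValueError("ShapMatrix/feature frame shape mismatch")
        p = pct.iloc[offset:offset + len(feats)]
        for i, (ridx, frow) in enumerate(feats.iterrows()):
            for j, name in enumerate(sm.feature_names):
                phi = sm.values[i, j]
                rows.append({
                    "subject": ridx,
                    "fold": sm.fold_index,
                    "feature": name,
                    "phi": phi,
                    "feature_value": frow[name],
                    "value_percentile": p.iloc[i][name],
                    "direction": (
                        "toward Ab-positive" if phi > 0
                        else "toward Ab-negative" if phi < 0 else "neutral"
                    ),
                })
        offset += len(feats)
    return pd.DataFrame(rows)
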