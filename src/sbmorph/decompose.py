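"""Source-based morphometry: spatial ICA of a GM cohort plus beta loadings.

The cohort matrix (subjects x masked voxels) is decomposed into K spatial
independent components (ICs) by fixed-point ICA.  Voxels play the role of
observations, so the recovered sources are spatial maps and the mixing
weights are per-subject coefficients.  Each subject's loading vector beta is
then (re-)estimated by ordinary least squares of the mean-centered voxel
vector on the K maps,

    I_GM = beta_1 IC_1 + beta_2 IC_2 + ... + beta_K IC_K,

so loadings are defined identically for fitting-cohort and held-out
subjects; beta_k behaves as a "weighted total gray matter volume" of the
brain pattern carried by IC_k.

ICA leaves sign and order indeterminate; deterministic conventions:

* sign — each map is flipped so its skewness over masked voxels is
  non-negative (tie-break: the maximum-|weight| voxel is positive);
* order — components are sorted by descending variance of their subject
  loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .volumes import BrainMask, FlatMatrix, GMVolume, flatten_volumes, unflatten

__all__ = [
    "ComponentSet",
    "ZMap",
    "decompose",
    "estimate_loadings",
    "zscore_component",
    "component_stability",
    "align_components",
]


@dataclass
class ComponentSet:
    """K spatial ICs with per-subject beta loadings.

    ``maps`` is K x masked-voxels, ``loadings`` subjects x K (the OLS betas
    of the fitting cohort), ``train_mean`` the voxel-wise mean image removed
    before ICA and before every projection.
    """

    maps: np.ndarray
    loadings: np.ndarray
    train_mean: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]
    fit_seed: int
    subject_ids: list[str] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.maps.ndim != 2 or self.loadings.ndim != 2:
            raise ValueError("maps and loadings must be 2D")
        if self.maps.shape[0] != self.loadings.shape[1]:
            raise ValueError("loadings column count must equal number of maps")
        if np.any(np.ptp(self.maps, axis=1) == 0):
            raise ValueError("a component map is constant")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    def map_volume(self, index: int) -> np.ndarray:
        """Component ``index`` folded back into the 3D grid."""
        return unflatten(self.maps[index], self.voxel_index, self.grid_shape)


@dataclass
class ZMap:
    """Z-scored component map with sub-threshold voxels zeroed."""

    z: np.ndarray
    threshold: float
    component_index: int
    n_surviving: int


def _as_matrix(volumes_or_matrix, mask: BrainMask | None) -> FlatMatrix:
    if isinstance(volumes_or_matrix, FlatMatrix):
        return volumes_or_matrix
    if mask is None:
        raise ValueError("a BrainMask is required when passing raw volumes")
    return flatten_volumes(volumes_or_matrix, mask)


def _canonicalize(maps: np.ndarray, loadings: np.ndarray):
    """Apply the sign and ordering conventions in place-free fashion."""
    maps = maps.copy()
    loadings = loadings.copy()
    skew = sps.skew(maps, axis=1)
    flip = skew < 0
    near_zero = np.abs(skew) < 1e-8
    if np.any(near_zero):
        peak = maps[near_zero, np.argmax(np.abs(maps[near_zero]), axis=1)]
        flip[near_zero] = peak < 0
    maps[flip] *= -1.0
    loadings[:, flip] *= -1.0
    order = np.argsort(-loadings.var(axis=0), kind="stable")
    return maps[order], loadings[:, order]


def decompose(
    matrix_or_volumes,
    K: int,
    seed: int = 0,
    mask: BrainMask | None = None,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> ComponentSet:
    """Fixed-point ICA of the (centered) cohort matrix into K spatial maps.

    The matrix is centered voxel-wise over subjects (the mean image is stored
    as ``train_mean``), transposed so voxels are ICA observations, and
    decomposed with scikit-learn's FastICA.  Betas are re-estimated by OLS on
    the canonicalized maps so that :func:`estimate_loadings` applied to the
    fitting cohort reproduces ``ComponentSet.loadings`` exactly.

    Non-convergence within ``max_iter`` iterations is recorded on the result
    (``converged=False``), not raised.
    """
    matrix = _as_matrix(matrix_or_volumes, mask)
    n_sub, n_vox = matrix.data.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_sub - 1:
        raise ValueError(
            f"K={K} exceeds the rank limit n_subjects-1={n_sub - 1}"
        )
    if np.any(np.ptp(matrix.data, axis=1) == 0):
        raise ValueError("matrix contains an all-constant subject row")

    train_mean = matrix.data.mean(axis=0)
    centered = matrix.data - train_mean

    ica = FastICA(
        n_components=K,
        random_state=seed,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        # voxels as observations -> sources are spatial maps
        sources = ica.fit_transform(centered.T)  # n_vox x K
    converged = not any(
        issubclass(w.category, ConvergenceWarning) for w in caught
    )

    mixing = ica.mixing_  # n_sub x K
    # FastICA additionally removes each subject's voxel mean; re-estimate the
    # spatial sources in the voxel-centered space so that the maps span the
    # centered data's row space (exact reconstruction at K = true rank).
    maps = np.linalg.pinv(mixing) @ centered  # K x n_vox
    # unit voxel variance per map: betas become comparable across components
    maps /= maps.std(axis=1, keepdims=True)
    maps, _ = _canonicalize(maps, mixing)
    loadings = _project(centered, maps)
    # loading variance can reorder after OLS; re-sort on the final betas
    order = np.argsort(-loadings.var(axis=0), kind="stable")
    maps = maps[order]
    loadings = loadings[:, order]

    return ComponentSet(
        maps=maps,
        loadings=loadings,
        train_mean=train_mean,
        voxel_index=matrix.voxel_index,
        grid_shape=matrix.grid_shape,
        fit_seed=seed,
        subject_ids=list(matrix.subject_ids),
        converged=converged,
        n_iter=int(getattr(ica, "n_iter_", 0)),
    )


def _project(centered: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """OLS betas of each centered voxel row on the maps (no intercept)."""
    gram = maps @ maps.T
    try:
        sol = np.linalg.solve(gram, maps @ centered.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "component map matrix is rank deficient; betas are not "
            "identifiable"
        ) from exc
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"component map matrix is near-singular (cond={cond:.3g})"
        )
    return sol.T


def estimate_loadings(
    volumes_or_matrix,
    components: ComponentSet,
    mask: BrainMask | None = None,
) -> np.ndarray:
    """Per-subject OLS betas on the fitted component maps.

    Subtracts the fitting cohort's ``train_mean`` and solves the no-intercept
    least-squares problem ``x_centered ~ maps``.  Works for both the fitting
    cohort and held-out subjects.
    """
    matrix = _as_matrix(volumes_or_matrix, mask)
    if matrix.data.shape[1] != components.maps.shape[1]:
        raise ValueError(
            f"voxel dimension {matrix.data.shape[1]} does not match the "
            f"component maps ({components.maps.shape[1]})"
        )
    centered = matrix.data - components.train_mean
    return _project(centered, components.maps)


def zscore_component(
    components: ComponentSet,
    index: int,
    threshold: float = 1.0,
    mask: BrainMask | None = None,
) -> ZMap:
    """Z-score one component map and zero voxels below ``threshold``.

    z = (value - mean) / SD over masked voxels; voxels with z < threshold
    are set to 0 in the returned 3D grid.
    """
    if not 0 <= index < components.K:
        raise IndexError(f"component index {index} out of range")
    values = components.maps[index]
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError("component map is constant (SD = 0)")
    z = (values - values.mean()) / sd
    keep = z >= threshold
    z_thr = np.where(keep, z, 0.0)
    grid = unflatten(z_thr, components.voxel_index, components.grid_shape)
    return ZMap(
        z=grid,
        threshold=float(threshold),
        component_index=int(index),
        n_surviving=int(keep.sum()),
    )


def align_components(
    maps_a: np.ndarray, maps_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal permutation/sign matching of two map sets.

    Hungarian assignment on the |correlation| matrix between rows of
    ``maps_a`` and ``maps_b``.  Returns (row indices into a, matched column
    indices into b, signed correlations of the matched pairs).
    """
    a = maps_a - maps_a.mean(axis=1, keepdims=True)
    b = maps_b - maps_b.mean(axis=1, keepdims=True)
    a = a / np.linalg.norm(a, axis=1, keepdims=True)
    b = b / np.linalg.norm(b, axis=1, keepdims=True)
    corr = a @ b.T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    return rows, cols, corr[rows, cols]


def component_stability(
    matrix_or_volumes,
    K: int,
    n_runs: int = 5,
    seeds: list[int] | None = None,
    mask: BrainMask | None = None,
) -> dict:
    """Split-half-style stability of the decomposition across ICA reruns.

    Decomposes the same matrix ``n_runs`` times with different seeds, aligns
    every later run's maps to the first run's, and reports per-component mean
    absolute matched correlation (1.0 = perfectly stable).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    matrix = _as_matrix(matrix_or_volumes, mask)
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("seeds length must equal n_runs")
    runs = [decompose(matrix, K, seed=s) for s in seeds]
    ref = runs[0].maps
    per_component = np.zeros(K)
    pair_corrs = []
    for run in runs[1:]:
        rows, cols, corr = align_components(ref, run.maps)
        aligned = np.empty(K)
        aligned[rows] = np.abs(corr)
        per_component += aligned
        pair_corrs.append(aligned)
    per_component /= n_runs - 1
    return {
        "per_component": per_component,
        "mean_stability": float(per_component.mean()),
        "pairwise": np.array(pair_corrs),
        "seeds": list(seeds),
        "converged": [r.converged for r in runs],
    }
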